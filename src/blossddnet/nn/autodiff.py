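"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the primitives the dual-task segmentation
network needs -- 2-D convolution (dense, dilated and depthwise),
transposed convolution, max pooling, batch normalisation, channel
gating and the elementwise/reduction ops used by the losses.  Arrays
are float32 NCHW; gradients are accumulated on a topologically sorted
tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "concat"]


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def _toposort(self):
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        return topo

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo = self._toposort()
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        # the graph is consumed: break the closure<->tensor reference cycles
        # so intermediates free by refcount instead of waiting for the GC
        for t in topo:
            t._backward = None
            t._parents = ()

    def release(self):
        """Drop the autodiff graph below this tensor (forward-only use)."""
        for t in self._toposort():
            t._backward = None
            t._parents = ()

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data / other.data, parents=(self, other))

            def bwd():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(
                        _unbroadcast(
                            -out.grad * self.data / (other.data * other.data),
                            other.data.shape,
                        )
                    )

            out._backward = bwd
            return out
        return self * (1.0 / float(other))

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad, self.data.shape))

        out._backward = bwd
        return out

    def mean(self):
        return self.sum() / self.data.size

    # -- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = bwd
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        out = Tensor(s, parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bwd
        return out

    def clamp(self, lo, hi):
        clipped = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(clipped, parents=(self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = bwd
        return out

    # -- gathers ---------------------------------------------------------
    def gather_flat(self, flat_index):
        """Pick elements by flat index (used by the bending-loss gradient path)."""
        idx = np.asarray(flat_index, dtype=np.intp)
        out = Tensor(self.data.reshape(-1)[idx], parents=(self,))

        def bwd():
            if self.requires_grad:
                g = np.zeros(self.data.size, dtype=np.float32)
                np.add.at(g, idx, out.grad)
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other):
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bwd
        return out

    # -- NCHW ops --------------------------------------------------------
    def channel_scale(self, scale):
        """Multiply (N,C,H,W) features by per-sample per-channel gains (N,C)."""
        s = scale.data[:, :, None, None]
        out = Tensor(self.data * s, parents=(self, scale))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * s)
            if scale.requires_grad:
                scale._accum((out.grad * self.data).sum(axis=(2, 3)))

        out._backward = bwd
        return out

    def global_avg_pool(self):
        """(N,C,H,W) -> (N,C) spatial mean."""
        n, c, h, w = self.data.shape
        out = Tensor(self.data.mean(axis=(2, 3)), parents=(self,))

        def bwd():
            if self.requires_grad:
                g = out.grad[:, :, None, None] / (h * w)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def pad2d(self, pt, pb, pl, pr, mode="constant"):
        out_data = np.pad(
            self.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)), mode=mode
        )
        out = Tensor(out_data, parents=(self,))
        h, w = self.data.shape[2:]

        def bwd():
            if not self.requires_grad:
                return
            if mode == "constant":
                self._accum(out.grad[:, :, pt : pt + h, pl : pl + w].copy())
                return
            # fold every padded cell's gradient back onto its source pixel
            idx = np.pad(
                np.arange(h * w).reshape(h, w), ((pt, pb), (pl, pr)), mode=mode
            ).ravel()
            n, c = self.data.shape[:2]
            g = np.zeros((n, c, h * w), dtype=np.float32)
            np.add.at(
                g, (slice(None), slice(None), idx), out.grad.reshape(n, c, -1)
            )
            self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def crop2d(self, top, left, height, width):
        out = Tensor(
            self.data[:, :, top : top + height, left : left + width].copy(),
            parents=(self,),
        )

        def bwd():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, :, top : top + height, left : left + width] = out.grad
                self._accum(g)

        out._backward = bwd
        return out


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad, dilation):
    """(N,C,H,W) -> (N, C, kh, kw, OH, OW) window view (copied)."""
    n, c, h, w = x.shape
    eh, ew = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    oh = (h + 2 * pad - eh) // stride + 1
    ow = (w + 2 * pad - ew) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(view), oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad, dilation):
    """Scatter-add the inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    oh, ow = cols.shape[4], cols.shape[5]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        di = i * dilation
        for j in range(kw):
            dj = j * dilation
            xp[
                :, :, di : di + stride * oh : stride, dj : dj + stride * ow : stride
            ] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x, w, b, stride=1, pad=0, dilation=1, depthwise=False):
    """2-D convolution.

    ``w`` is (OC, IC, kh, kw); for ``depthwise`` it is (C, 1, kh, kw) and the
    convolution is applied per channel.
    """
    kh, kw = w.data.shape[2:]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad, dilation)
    n, c = cols.shape[:2]
    if depthwise:
        cr = cols.reshape(n, c, kh * kw, oh * ow)
        wr = w.data.reshape(c, kh * kw)
        out_data = np.einsum("nckl,ck->ncl", cr, wr, optimize=True)
        out_data = out_data.reshape(n, c, oh, ow)
    else:
        oc = w.data.shape[0]
        cr = cols.reshape(n, c * kh * kw, oh * ow)
        wr = w.data.reshape(oc, c * kh * kw)
        out_data = np.matmul(wr, cr).reshape(n, oc, oh, ow)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, parents=parents)

    def bwd():
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gl = g.reshape(n, g.shape[1], oh * ow)
        if depthwise:
            if w.requires_grad:
                w._accum(
                    np.einsum("ncl,nckl->ck", gl, cr, optimize=True).reshape(
                        w.data.shape
                    )
                )
            if x.requires_grad:
                gcols = np.einsum(
                    "ncl,ck->nckl", gl, w.data.reshape(c, kh * kw), optimize=True
                ).reshape(n, c, kh, kw, oh, ow)
                x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad, dilation))
        else:
            wr = w.data.reshape(w.data.shape[0], c * kh * kw)
            if w.requires_grad:
                gw = np.einsum("nol,nkl->ok", gl, cr, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = np.matmul(wr.T, gl).reshape(n, c, kh, kw, oh, ow)
                x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad, dilation))

    out._backward = bwd
    return out


def conv_transpose2d_2x2(x, w, b):
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    ``w`` is (IC, OC, 2, 2).
    """
    n, ic, h, ww_ = x.data.shape
    oc = w.data.shape[1]
    t = np.einsum("nihw,ioab->nohawb", x.data, w.data, optimize=True)
    out_data = t.reshape(n, oc, 2 * h, 2 * ww_)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, parents=parents)

    def bwd():
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        g6 = g.reshape(n, oc, h, 2, ww_, 2)
        if x.requires_grad:
            x._accum(np.einsum("nohawb,ioab->nihw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("nihw,nohawb->ioab", x.data, g6, optimize=True))

    out._backward = bwd
    return out


def maxpool2d(x, kernel, stride, pad=0):
    """Max pooling with -inf padding; gradients flow to the argmax only."""
    n, c, h, w = x.data.shape
    if pad:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    cols, oh, ow = _im2col(xp, kernel, kernel, stride, 0, 1)
    cr = cols.reshape(n, c, kernel * kernel, oh * ow)
    idx = cr.argmax(axis=2)
    out_data = np.take_along_axis(cr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(out_data.reshape(n, c, oh, ow), parents=(x,))

    def bwd():
        if not x.requires_grad:
            return
        gcr = np.zeros_like(cr)
        np.put_along_axis(
            gcr, idx[:, :, None, :], out.grad.reshape(n, c, 1, oh * ow), axis=2
        )
        gcols = gcr.reshape(n, c, kernel, kernel, oh, ow)
        gxp = _col2im(gcols, xp.shape, kernel, kernel, stride, 0, 1)
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        x._accum(gxp)

    out._backward = bwd
    return out


def batch_norm(x, gamma, beta, running_mean, running_var, training, momentum=0.1,
               eps=1e-5):
    """Batch normalisation over (N,H,W) per channel.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    during training.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd():
        g = out.grad
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                mean_g = gi.mean(axis=(0, 2, 3))[None, :, None, None]
                mean_gx = (gi * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                dx = inv_std[None, :, None, None] * (gi - mean_g - xhat * mean_gx)
            else:
                dx = gi * inv_std[None, :, None, None]
            x._accum(dx)
        _ = m  # reduction size folded into the means above

    out._backward = bwd
    return out
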