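"""Layer/module system built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    batch_norm,
    conv2d,
    conv_transpose2d_2x2,
    maxpool2d,
)

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d",
    "SEBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module container: parameter registry plus train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def parameter_count(self):
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ------------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_bn(""):
            state[f"{name}.running_mean"] = m.running_mean.copy()
            state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for name, m in self._named_bn(""):
            m.running_mean = np.asarray(
                state[f"{name}.running_mean"], dtype=np.float32
            )
            m.running_var = np.asarray(
                state[f"{name}.running_var"], dtype=np.float32
            )

    def _named_bn(self, prefix):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, BatchNorm2d):
                yield full, val
            elif isinstance(val, Module):
                yield from val._named_bn(full)
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_bn(f"{full}.{k}")


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, pad=None, dilation=1,
                 depthwise=False, bias=True):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError(f"invalid channel counts in={in_ch}, out={out_ch}")
        if depthwise and in_ch != out_ch:
            raise ValueError("depthwise convolution requires in_ch == out_ch")
        self.stride = stride
        self.dilation = dilation
        self.depthwise = depthwise
        # 'same' padding for stride 1 by default
        self.pad = dilation * (kernel - 1) // 2 if pad is None else pad
        wshape = (
            (in_ch, 1, kernel, kernel)
            if depthwise
            else (out_ch, in_ch, kernel, kernel)
        )
        fan_in = (1 if depthwise else in_ch) * kernel * kernel
        self.weight = Parameter(_he_normal(rng, wshape, fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(
            x, self.weight, self.bias,
            stride=self.stride, pad=self.pad, dilation=self.dilation,
            depthwise=self.depthwise,
        )


class ConvTranspose2x2(Module):
    """Transposed convolution, kernel 2 stride 2 (the upsampling step)."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        return conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x):
        return x.matmul(self.weight) + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel, stride, pad=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        return maxpool2d(x, self.kernel, self.stride, self.pad)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate (reduction ratio default 16)."""

    def __init__(self, channels, rng, reduction=16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.force_gate = None  # test hook: None | float

    def forward(self, x):
        if self.force_gate is not None:
            gains = np.full(
                (x.shape[0], x.shape[1]), self.force_gate, dtype=np.float32
            )
            return x.channel_scale(Tensor(gains))
        s = x.global_avg_pool()
        s = self.fc1(s).relu()
        s = self.fc2(s).sigmoid()
        return x.channel_scale(s)
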