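"""Contour extraction and discrete bending energy.

A nucleus boundary is an ordered, implicitly closed polygon of pixel
coordinates.  At each vertex the unsigned turning curvature is

    k(i) = 2*|v_prev x v_next| / (|v_prev|*|v_next| + v_prev . v_next)
         = 2*tan(theta_i / 2),

where ``v_prev = A_i - A_{i-1}``, ``v_next = A_{i+1} - A_i`` (cyclic) and
``theta_i`` is the turning angle.  The discrete bending energy at a vertex
divides the squared curvature by the summed adjacent edge lengths,

    BE(i) = k(i)^2 / (|v_prev| + |v_next|),

a discretisation of the continuous bending energy integral of curvature
squared along the curve.  Contours whose turning angle reaches pi (an exact
reversal) have an unbounded k; it is capped at ``K_MAX`` with a warning so
downstream losses stay finite on ragged rasterised boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "K_MAX",
    "Contour",
    "CurvatureProfile",
    "trace_contours",
    "edge_vectors",
    "turning_curvature",
    "bending_energy",
    "gt_boundary_map",
]

K_MAX = 1e3

# Moore neighbourhood in clockwise order on screen (row down), starting west.
_DIRS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}


class DegenerateContourError(ValueError):
    """Raised when an operation needs at least 3 vertices."""


@dataclass
class Contour:
    """Ordered closed polygon of boundary coordinates (row, col)."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be (m, 2), got shape {v.shape}")
        if len(v) > 1:
            same = np.all(v == np.roll(v, -1, axis=0), axis=1)
            if same.any():
                raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    @property
    def m(self) -> int:
        return len(self.vertices)


@dataclass
class CurvatureProfile:
    """Per-vertex curvature and bending energy of one contour."""

    k: np.ndarray
    be: np.ndarray
    total_be: float = field(init=False)
    mean_be: float = field(init=False)

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        self.be = np.asarray(self.be, dtype=float)
        if self.k.shape != self.be.shape:
            raise ValueError("k and be must have equal length")
        self.total_be = float(self.be.sum())
        self.mean_be = self.total_be / len(self.be)

    @property
    def m(self) -> int:
        return len(self.k)


def _validate_binary(mask):
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got ndim={mask.ndim}")
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"mask must contain only 0/1, found values {bad.tolist()}")
    return mask.astype(bool)


def _moore_trace(bw, start):
    """Trace the outer border of one 8-connected component.

    ``bw`` is a bool array padded with a 1-pixel false border so neighbour
    lookups never leave the array; ``start`` is the uppermost-leftmost
    component pixel.  Jacob's stopping criterion: terminate on re-entering
    the start pixel with the same next move as the first step.
    """
    r0, c0 = start
    prev = (r0, c0 - 1)  # scan order guarantees the west neighbour is empty
    vertices = []
    cur = start
    first_move = None
    max_steps = 4 * int(bw.sum()) + 8
    for _ in range(max_steps):
        b = _DIR_INDEX[(prev[0] - cur[0], prev[1] - cur[1])]
        found = None
        last_bg = prev
        for i in range(1, 9):
            d = _DIRS[(b + i) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if bw[cand]:
                found = cand
                break
            last_bg = cand
        if found is None:  # isolated pixel
            return [cur]
        if cur == start:
            if first_move is None:
                first_move = found
            elif found == first_move:
                break
        vertices.append(cur)
        prev = last_bg
        cur = found
    return vertices


def trace_contours(mask, min_length=1):
    """Extract one outer contour per 8-connected foreground component.

    Components whose traced contour has fewer than ``min_length`` vertices
    are dropped.  Holes are ignored (nuclei are simply connected).
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    bw = _validate_binary(mask)
    if not bw.any():
        return []
    labels, n = ndimage.label(bw, structure=np.ones((3, 3), dtype=int))
    padded = np.pad(labels, 1)
    contours = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        comp = padded == lab
        rows, cols = np.nonzero(comp)
        order = np.lexsort((cols, rows))
        start = (int(rows[order[0]]), int(cols[order[0]]))
        verts = _moore_trace(comp, start)
        if len(verts) >= min_length:
            contours.append(Contour(np.asarray(verts, dtype=float) - 1.0))
    return contours


def edge_vectors(contour, i):
    """Side vectors at vertex ``i``: ``v_prev = A_i - A_{i-1}``,
    ``v_next = A_{i+1} - A_i`` with cyclic indexing."""
    v = contour.vertices
    m = len(v)
    if m < 3:
        raise DegenerateContourError(f"need m >= 3 vertices, got {m}")
    v_prev = v[i] - v[(i - 1) % m]
    v_next = v[(i + 1) % m] - v[i]
    return v_prev, v_next


def _edge_arrays(contour):
    v = contour.vertices
    if len(v) < 3:
        raise DegenerateContourError(f"need m >= 3 vertices, got {len(v)}")
    v_next = np.roll(v, -1, axis=0) - v
    v_prev = np.roll(v_next, 1, axis=0)
    return v_prev, v_next


def turning_curvature(contour, k_max=K_MAX):
    """Unsigned turning curvature ``k(i) = 2 tan(theta_i/2)`` per vertex."""
    vp, vn = _edge_arrays(contour)
    cross = np.abs(vp[:, 0] * vn[:, 1] - vp[:, 1] * vn[:, 0])
    lp = np.hypot(vp[:, 0], vp[:, 1])
    ln = np.hypot(vn[:, 0], vn[:, 1])
    denom = lp * ln + (vp * vn).sum(axis=1)
    k = np.empty(len(vp))
    tiny = 1e-12 * np.maximum(lp * ln, 1.0)
    reversal = denom <= tiny
    if reversal.any():
        warnings.warn(
            f"{int(reversal.sum())} reversal vertices (turning angle pi); "
            f"curvature capped at {k_max:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    k[~reversal] = 2.0 * cross[~reversal] / denom[~reversal]
    k[reversal] = k_max
    return np.minimum(k, k_max)


def bending_energy(contour, k_max=K_MAX):
    """Per-vertex bending energy ``BE(i) = k(i)^2 / (|v_prev| + |v_next|)``."""
    vp, vn = _edge_arrays(contour)
    k = turning_curvature(contour, k_max=k_max)
    lengths = np.hypot(vp[:, 0], vp[:, 1]) + np.hypot(vn[:, 0], vn[:, 1])
    return CurvatureProfile(k=k, be=k * k / lengths)


def gt_boundary_map(instances, thickness=2):
    """Boundary ground truth: instance pixels with a 4-neighbour of a
    different label (background included), dilated to ``thickness``.

    Touching instances produce boundary on both sides of their shared edge
    even with no background gap.
    """
    if thickness < 1:
        raise ValueError(f"thickness must be >= 1, got {thickness}")
    lab = np.asarray(instances)
    if lab.ndim != 2:
        raise ValueError(f"instance map must be 2-D, got ndim={lab.ndim}")
    if lab.size and lab.min() < 0:
        raise ValueError("instance labels must be nonnegative")
    b = np.zeros(lab.shape, dtype=bool)
    dv = lab[:-1, :] != lab[1:, :]
    b[:-1, :] |= dv
    b[1:, :] |= dv
    dh = lab[:, :-1] != lab[:, 1:]
    b[:, :-1] |= dh
    b[:, 1:] |= dh
    b &= lab > 0
    if thickness > 1:
        structure = ndimage.generate_binary_structure(2, 1)
        b = ndimage.binary_dilation(b, structure=structure, iterations=thickness - 1)
    return b.astype(np.uint8)
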