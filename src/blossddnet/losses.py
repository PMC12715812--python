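"""Training objectives: BCE, Dice, bending loss, and their composite.

The composite objective weights pixel-wise binary cross-entropy (alpha),
Dice loss (beta) and the bending loss (gamma) with defaults
alpha=0.4, beta=0.3, gamma=0.3.  During decoder architecture search the
mask branch instead uses 0.3*BCE + 0.7*Dice.

Two readings of the composite are provided.  ``mode="literal"`` applies
BCE+Dice to the mask branch only and the bending loss to the boundary
branch, exactly as the closed-form objective is written.  Read that way the
boundary branch receives no pixel-wise ground truth and would collapse to
empty predictions, so the default ``mode="supervised"`` additionally applies
alpha*BCE + beta*Dice against the boundary ground truth on the boundary
branch.  Both modes are kept because the intended reading is genuinely
ambiguous.

The bending loss binarizes the predicted boundary map, traces the contours
of the result and averages the discrete bending energy over all contour
vertices.  Contour tracing is not differentiable; with ``prob_weighted``
(the default gradient path during training) each vertex's bending energy is
multiplied by the predicted probability at that pixel, so gradients flow
through the vertex terms and high-curvature kinks push their own pixels'
boundary probability down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import K_MAX, bending_energy, trace_contours
from .nn.autodiff import Tensor

__all__ = [
    "LossWeights",
    "LossReport",
    "bce_loss",
    "dice_loss",
    "nas_mask_loss",
    "bending_loss_term",
    "total_loss",
    "bce_loss_tensor",
    "dice_loss_tensor",
    "bending_loss_tensor",
    "total_loss_tensor",
]

DEFAULT_MIN_CONTOUR = 8
# Sharpest turning angle an 8-connected grid contour can legitimately take is
# 135 degrees; anything above that level (up to the reversal cap K_MAX) is a
# one-pixel spur artifact.  The differentiable loss path caps k there so spur
# vertices cannot dominate the gradient.
K_MAX_GRID = 2.0 * np.tan(3.0 * np.pi / 8.0)


@dataclass
class LossWeights:
    """Weights of the composite objective and the NAS-phase mask loss."""

    alpha: float = 0.4
    beta: float = 0.3
    gamma: float = 0.3
    mask_bce_weight: float = 0.3
    mask_dice_weight: float = 0.7
    bce_eps: float = 1e-7
    dice_eps: float = 1e-6

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "mask_bce_weight", "mask_dice_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LossReport:
    """Component values of one composite-loss evaluation."""

    l_bce: float
    l_dsc: float
    l_bend: float
    mask_branch: float
    boundary_branch: float
    total: float
    mode: str
    boundary_bce: float = 0.0
    boundary_dice: float = 0.0
    extras: dict = field(default_factory=dict)


def _check_pair(pred, gt):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not np.isfinite(pred).all():
        raise ValueError("prediction contains non-finite values")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")
    bad = np.setdiff1d(np.unique(gt), [0, 1])
    if bad.size:
        raise ValueError(f"ground truth must be binary, found values {bad.tolist()}")
    return pred, gt.astype(np.float64)


# ---------------------------------------------------------------------------
# tensor-level forms (used by training; the float API wraps these)
# ---------------------------------------------------------------------------

def bce_loss_tensor(pred: Tensor, gt: np.ndarray, eps: float = 1e-7) -> Tensor:
    y = np.asarray(gt, dtype=np.float32)
    p = pred.clamp(eps, 1.0 - eps)
    term = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -(term.mean())


def dice_loss_tensor(pred: Tensor, gt: np.ndarray, eps: float = 1e-6) -> Tensor:
    y = Tensor(np.asarray(gt, dtype=np.float32))
    inter = (pred * y).sum() * 2.0 + eps
    denom = (y * y).sum() + (pred * pred).sum() + eps
    return 1.0 - inter / denom


def _bending_vertex_terms(prob, threshold, min_length, k_max=K_MAX):
    """Flat pixel indices and bending-energy values of all contour vertices."""
    bw = (np.asarray(prob) >= threshold).astype(np.uint8)
    idx, be = [], []
    for contour in trace_contours(bw, min_length=min_length):
        v = contour.vertices.astype(np.intp)
        flat = v[:, 0] * bw.shape[1] + v[:, 1]
        idx.append(flat)
        if contour.m >= 3:
            be.append(bending_energy(contour, k_max=k_max).be)
        else:
            be.append(np.zeros(contour.m))
    if not idx:
        return np.empty(0, dtype=np.intp), np.empty(0)
    return np.concatenate(idx), np.concatenate(be)


def bending_loss_tensor(
    pred: Tensor,
    threshold: float = 0.5,
    min_length: int = DEFAULT_MIN_CONTOUR,
    prob_weighted: bool = True,
    k_max: float = K_MAX_GRID,
) -> Tensor:
    """Bending loss with a gradient path through the vertex probabilities.

    The training path caps curvature at the sharpest legitimate grid corner
    (``K_MAX_GRID``) so one-pixel spurs do not dominate the gradient.
    """
    idx, be = _bending_vertex_terms(pred.data, threshold, min_length, k_max)
    if idx.size == 0:
        return Tensor(np.zeros(()))
    if prob_weighted:
        picked = pred.gather_flat(idx)
        return (picked * Tensor(be.astype(np.float32))).sum() / idx.size
    return Tensor(np.float32(be.mean()))


# ---------------------------------------------------------------------------
# float API
# ---------------------------------------------------------------------------

def bce_loss(pred, gt, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, predictions clamped to [eps, 1-eps]."""
    pred, y = _check_pair(pred, gt)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(pred, gt, eps: float = 1e-6) -> float:
    """Smoothed Dice loss with squared-sum denominator:
    1 - (2*sum(y*p) + eps) / (sum(y^2) + sum(p^2) + eps).

    The shared smoothing term makes an exactly-empty prediction of an empty
    ground truth cost 0 instead of 1 (and keeps the gradient finite there);
    for nonempty ground truth it perturbs the loss by at most ~eps.
    """
    pred, y = _check_pair(pred, gt)
    inter = 2.0 * float((pred * y).sum()) + eps
    denom = float((y * y).sum() + (pred * pred).sum()) + eps
    return 1.0 - inter / denom


def nas_mask_loss(pred, gt, weights: LossWeights | None = None) -> float:
    """Architecture-search mask objective: 0.3*BCE + 0.7*Dice by default."""
    w = weights or LossWeights()
    return w.mask_bce_weight * bce_loss(pred, gt, w.bce_eps) + w.mask_dice_weight * dice_loss(
        pred, gt, w.dice_eps
    )


def bending_loss_term(
    pred_boundary,
    threshold: float = 0.5,
    prob_weighted: bool = False,
    min_length: int = DEFAULT_MIN_CONTOUR,
    k_max: float = K_MAX,
) -> float:
    """Mean discrete bending energy over all traced boundary-contour vertices.

    Returns 0 when no contour of at least ``min_length`` vertices survives
    binarization (an empty boundary prediction is a defined, stable case).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    prob = np.asarray(pred_boundary, dtype=np.float64)
    idx, be = _bending_vertex_terms(prob, threshold, min_length, k_max)
    if idx.size == 0:
        return 0.0
    if prob_weighted:
        return float((be * prob.reshape(-1)[idx]).sum() / idx.size)
    return float(be.mean())


def total_loss(
    mask_pred,
    mask_gt,
    boundary_pred,
    boundary_gt,
    weights: LossWeights | None = None,
    mode: str = "supervised",
) -> LossReport:
    """Composite objective over both branches.

    ``literal``: total = alpha*BCE(mask) + beta*Dice(mask) + gamma*Bend(boundary).
    ``supervised`` (default): adds alpha*BCE + beta*Dice against the boundary
    ground truth so the boundary branch is trainable.
    """
    w = weights or LossWeights()
    if mode not in ("literal", "supervised"):
        raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'supervised'")
    l_bce = bce_loss(mask_pred, mask_gt, w.bce_eps)
    l_dsc = dice_loss(mask_pred, mask_gt, w.dice_eps)
    l_bend = bending_loss_term(boundary_pred)
    mask_branch = w.alpha * l_bce + w.beta * l_dsc
    if mode == "literal":
        b_bce = b_dsc = 0.0
        boundary_branch = w.gamma * l_bend
    else:
        b_bce = bce_loss(boundary_pred, boundary_gt, w.bce_eps)
        b_dsc = dice_loss(boundary_pred, boundary_gt, w.dice_eps)
        boundary_branch = w.alpha * b_bce + w.beta * b_dsc + w.gamma * l_bend
    return LossReport(
        l_bce=l_bce,
        l_dsc=l_dsc,
        l_bend=l_bend,
        mask_branch=mask_branch,
        boundary_branch=boundary_branch,
        total=mask_branch + boundary_branch,
        mode=mode,
        boundary_bce=b_bce,
        boundary_dice=b_dsc,
    )


def bending_loss_tensor_batch(
    pred: Tensor,
    threshold: float = 0.5,
    min_length: int = DEFAULT_MIN_CONTOUR,
    prob_weighted: bool = True,
    k_max: float = K_MAX_GRID,
) -> Tensor:
    """Bending loss over an (N,1,H,W) batch: one contour trace per image,
    averaged over all vertices of all images."""
    n, _, h, w = pred.shape
    plane = h * w
    all_idx, all_be = [], []
    for i in range(n):
        idx, be = _bending_vertex_terms(pred.data[i, 0], threshold, min_length, k_max)
        if idx.size:
            all_idx.append(idx + i * plane)
            all_be.append(be)
    if not all_idx:
        return Tensor(np.zeros(()))
    idx = np.concatenate(all_idx)
    be = np.concatenate(all_be)
    if prob_weighted:
        picked = pred.gather_flat(idx)
        return (picked * Tensor(be.astype(np.float32))).sum() / idx.size
    return Tensor(np.float32(be.mean()))


def total_loss_tensor_batch(
    mask_pred: Tensor,
    mask_gt,
    boundary_pred: Tensor,
    boundary_gt,
    weights: LossWeights | None = None,
    mode: str = "supervised",
):
    """Batched differentiable composite loss -> (scalar Tensor, LossReport).

    BCE/Dice reduce over the whole (N,1,H,W) batch; the bending term traces
    each image separately and averages over all vertices.
    """
    w = weights or LossWeights()
    if mode not in ("literal", "supervised"):
        raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'supervised'")
    l_bce = bce_loss_tensor(mask_pred, mask_gt, w.bce_eps)
    l_dsc = dice_loss_tensor(mask_pred, mask_gt, w.dice_eps)
    l_bend = bending_loss_tensor_batch(boundary_pred)
    total = l_bce * w.alpha + l_dsc * w.beta
    b_bce_v = b_dsc_v = 0.0
    if mode == "supervised":
        b_bce = bce_loss_tensor(boundary_pred, boundary_gt, w.bce_eps)
        b_dsc = dice_loss_tensor(boundary_pred, boundary_gt, w.dice_eps)
        total = total + b_bce * w.alpha + b_dsc * w.beta
        b_bce_v, b_dsc_v = b_bce.item(), b_dsc.item()
    total = total + l_bend * w.gamma
    mask_branch = w.alpha * l_bce.item() + w.beta * l_dsc.item()
    report = LossReport(
        l_bce=l_bce.item(),
        l_dsc=l_dsc.item(),
        l_bend=l_bend.item(),
        mask_branch=mask_branch,
        boundary_branch=total.item() - mask_branch,
        total=total.item(),
        mode=mode,
        boundary_bce=b_bce_v,
        boundary_dice=b_dsc_v,
    )
    return total, report


def total_loss_tensor(
    mask_pred: Tensor,
    mask_gt,
    boundary_pred: Tensor,
    boundary_gt,
    weights: LossWeights | None = None,
    mode: str = "supervised",
):
    """Differentiable composite loss; returns (scalar Tensor, LossReport)."""
    w = weights or LossWeights()
    if mode not in ("literal", "supervised"):
        raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'supervised'")
    l_bce = bce_loss_tensor(mask_pred, mask_gt, w.bce_eps)
    l_dsc = dice_loss_tensor(mask_pred, mask_gt, w.dice_eps)
    l_bend = bending_loss_tensor(boundary_pred)
    total = l_bce * w.alpha + l_dsc * w.beta
    b_bce_v = b_dsc_v = 0.0
    if mode == "supervised":
        b_bce = bce_loss_tensor(boundary_pred, boundary_gt, w.bce_eps)
        b_dsc = dice_loss_tensor(boundary_pred, boundary_gt, w.dice_eps)
        total = total + b_bce * w.alpha + b_dsc * w.beta
        b_bce_v, b_dsc_v = b_bce.item(), b_dsc.item()
    total = total + l_bend * w.gamma
    mask_branch = w.alpha * l_bce.item() + w.beta * l_dsc.item()
    report = LossReport(
        l_bce=l_bce.item(),
        l_dsc=l_dsc.item(),
        l_bend=l_bend.item(),
        mask_branch=mask_branch,
        boundary_branch=total.item() - mask_branch,
        total=total.item(),
        mode=mode,
        boundary_bce=b_bce_v,
        boundary_dice=b_dsc_v,
    )
    return total, report
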