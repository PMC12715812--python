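"""Instance-segmentation evaluation: AJI, Dice and Panoptic Quality.

AJI (aggregated Jaccard index) walks ground-truth nuclei in ascending label
order; each is matched to the prediction with the largest Jaccard index, a
prediction can be consumed only once, and unmatched predictions add their
full area to the denominator:

    AJI = sum_i |G_i ∩ P_match(i)| / (sum_i |G_i ∪ P_match(i)| + sum_{k in U} |P_k|)

Dice is the semantic set overlap 2|G∩P|/(|G|+|P|) on binarized foreground.

PQ declares a (gt, pred) pair a true positive when IoU > 0.5 (which makes
matches automatically unique) and scores

    PQ = sum_TP IoU / (|TP| + 0.5*|FP| + 0.5*|FN|).

Conventions for empty maps: two empty maps are a perfect agreement
(AJI = Dice = PQ = 1); one-sided-empty comparisons score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MatchTable",
    "canonicalize",
    "iou",
    "dice_coefficient",
    "aji",
    "panoptic_quality",
    "evaluate_batch",
]


@dataclass
class MatchTable:
    """IoU>0.5 matching between ground-truth and predicted instances."""

    tp_pairs: list = field(default_factory=list)  # (gt_label, pred_label, iou)
    fp_labels: set = field(default_factory=set)
    fn_labels: set = field(default_factory=set)


def _check_shapes(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def canonicalize(labels):
    """Relabel instances to consecutive 1..n (order of first appearance of
    sorted original labels); 0 stays background."""
    lab = np.asarray(labels)
    if lab.size and lab.min() < 0:
        raise ValueError("instance labels must be nonnegative")
    vals = np.unique(lab)
    vals = vals[vals > 0]
    out = np.zeros_like(lab, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[lab == old] = new
    return out


def iou(a, b):
    """Intersection over union of two binary maps; 0 when both are empty."""
    a, b = _check_shapes(a, b)
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def dice_coefficient(gt, pred):
    """Semantic Dice 2|G∩P|/(|G|+|P|); both-empty defined as 1."""
    gt, pred = _check_shapes(gt, pred)
    g = gt.astype(bool)
    p = pred.astype(bool)
    denom = g.sum() + p.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(g, p).sum() / denom)


def _contingency(gt, pred):
    """Intersection-area matrix between positive gt and pred labels."""
    gt = canonicalize(gt)
    pred = canonicalize(pred)
    ng = int(gt.max())
    npr = int(pred.max())
    if ng and npr:
        pair = gt.astype(np.int64) * (npr + 1) + pred.astype(np.int64)
        counts = np.bincount(pair.ravel(), minlength=(ng + 1) * (npr + 1))
        inter = counts.reshape(ng + 1, npr + 1)[1:, 1:]
    else:
        inter = np.zeros((ng, npr), dtype=np.int64)
    g_areas = np.bincount(gt.ravel(), minlength=ng + 1)[1:]
    p_areas = np.bincount(pred.ravel(), minlength=npr + 1)[1:]
    return inter, g_areas, p_areas


def aji(gt, pred):
    """Aggregated Jaccard index with single-use predictions.

    Ground-truth instances are visited in ascending label order; ties on the
    best Jaccard index break toward the lower prediction label.  A
    ground-truth nucleus whose best prediction was already consumed
    contributes intersection 0 and union |G_i|.
    """
    gt, pred = _check_shapes(gt, pred)
    inter, g_areas, p_areas = _contingency(gt, pred)
    ng, npr = inter.shape
    if ng == 0 and npr == 0:
        return 1.0
    union = g_areas[:, None] + p_areas[None, :] - inter
    numerator = 0.0
    denominator = 0.0
    used = np.zeros(npr, dtype=bool)
    for i in range(ng):
        if npr:
            jac = inter[i] / union[i]
            k = int(np.argmax(jac))  # argmax takes the lowest index on ties
        else:
            k = -1
        if k >= 0 and not used[k] and inter[i, k] > 0:
            numerator += inter[i, k]
            denominator += union[i, k]
            used[k] = True
        elif k >= 0 and not used[k]:
            # best Jaccard is 0: consume nothing, count the gt area
            denominator += g_areas[i]
        else:
            denominator += g_areas[i]
    denominator += p_areas[~used].sum()
    if denominator == 0:
        return 0.0
    return float(numerator / denominator)


def panoptic_quality(gt, pred):
    """Panoptic quality with the IoU>0.5 unique-matching rule.

    Returns ``(pq, match_table)``.  Both-empty maps score 1; one-sided-empty
    maps score 0.
    """
    gt, pred = _check_shapes(gt, pred)
    inter, g_areas, p_areas = _contingency(gt, pred)
    ng, npr = inter.shape
    table = MatchTable()
    if ng == 0 and npr == 0:
        return 1.0, table
    union = g_areas[:, None] + p_areas[None, :] - inter
    matched_g = np.zeros(ng, dtype=bool)
    matched_p = np.zeros(npr, dtype=bool)
    iou_sum = 0.0
    for i in range(ng):
        for k in range(npr):
            if union[i, k] and inter[i, k] / union[i, k] > 0.5:
                iou_val = inter[i, k] / union[i, k]
                table.tp_pairs.append((i + 1, k + 1, float(iou_val)))
                matched_g[i] = True
                matched_p[k] = True
                iou_sum += iou_val
    table.fn_labels = {i + 1 for i in range(ng) if not matched_g[i]}
    table.fp_labels = {k + 1 for k in range(npr) if not matched_p[k]}
    tp = len(table.tp_pairs)
    denom = tp + 0.5 * len(table.fp_labels) + 0.5 * len(table.fn_labels)
    if denom == 0:
        return 0.0, table
    return float(iou_sum / denom), table


def _check_instance_map(m):
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"instance map must be 2-D, got ndim={m.ndim}")
    return m


def evaluate_batch(pairs):
    """Per-image and mean AJI/Dice/PQ over (gt, pred) instance-map pairs.

    Returns a DataFrame with one row per image plus a ``mean`` row; Dice is
    computed on the binarized union of instances.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty batch")
    rows = []
    for idx, (gt, pred) in enumerate(pairs):
        gt = _check_instance_map(gt)
        pred = _check_instance_map(pred)
        _check_shapes(gt, pred)
        pq, _ = panoptic_quality(gt, pred)
        rows.append(
            {
                "image_id": str(idx),
                "aji": aji(gt, pred),
                "dice": dice_coefficient(gt > 0, pred > 0),
                "pq": pq,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "image_id": "mean",
        "aji": df["aji"].mean(),
        "dice": df["dice"].mean(),
        "pq": df["pq"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def relabel_connected(mask):
    """Label 8-connected components of a binary mask as instances."""
    mask = np.asarray(mask).astype(bool)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels.astype(np.int32)
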