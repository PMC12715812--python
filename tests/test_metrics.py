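"""AJI, Dice, PQ against hand cases and a literal brute-force reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blossddnet.metrics import (
    aji,
    canonicalize,
    dice_coefficient,
    evaluate_batch,
    iou,
    panoptic_quality,
)


# ---------------------------------------------------------------------------
# independent brute-force reference implementations
# ---------------------------------------------------------------------------

def _instances_as_sets(labels):
    return {
        int(lab): set(map(tuple, np.argwhere(labels == lab)))
        for lab in np.unique(labels)
        if lab != 0
    }


def brute_force_aji(gt, pred):
    """Definition applied literally on pixel sets: visit GT nuclei in
    ascending label order, match each to the prediction with the largest
    Jaccard index, never reuse a prediction, and add unused prediction areas
    to the denominator."""
    g_sets = _instances_as_sets(gt)
    p_sets = _instances_as_sets(pred)
    if not g_sets and not p_sets:
        return 1.0
    used = set()
    num = den = 0.0
    for gl in sorted(g_sets):
        g = g_sets[gl]
        best_j, best_k = -1.0, None
        for pl in sorted(p_sets):
            p = p_sets[pl]
            j = len(g & p) / len(g | p)
            if j > best_j:
                best_j, best_k = j, pl
        if best_k is not None and best_k not in used and len(g & p_sets[best_k]) > 0:
            num += len(g & p_sets[best_k])
            den += len(g | p_sets[best_k])
            used.add(best_k)
        else:
            den += len(g)
    for pl, p in p_sets.items():
        if pl not in used:
            den += len(p)
    return num / den if den else 0.0


def brute_force_pq(gt, pred):
    """Literal PQ: every (gt, pred) pair with IoU > 0.5 is a TP."""
    g_sets = _instances_as_sets(gt)
    p_sets = _instances_as_sets(pred)
    if not g_sets and not p_sets:
        return 1.0
    tp, iou_sum = 0, 0.0
    matched_g, matched_p = set(), set()
    for gl, g in g_sets.items():
        for pl, p in p_sets.items():
            u = len(g | p)
            if u and len(g & p) / u > 0.5:
                tp += 1
                iou_sum += len(g & p) / u
                matched_g.add(gl)
                matched_p.add(pl)
    fp = len(p_sets) - len(matched_p)
    fn = len(g_sets) - len(matched_g)
    den = tp + 0.5 * fp + 0.5 * fn
    return iou_sum / den if den else 0.0


def random_label_map(rng, shape=(12, 12), max_instances=4):
    lab = np.zeros(shape, dtype=int)
    n = rng.integers(0, max_instances + 1)
    for k in range(1, n + 1):
        r, c = rng.integers(0, shape[0] - 3), rng.integers(0, shape[1] - 3)
        h, w = rng.integers(2, 5), rng.integers(2, 5)
        lab[r : r + h, c : c + w] = k
    return lab


class TestIou:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4))
        m[1:3, 1:3] = 1
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1
        b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_hand_count(self):
        # areas 4 and 4 overlapping in 2 -> 2/6
        a = np.zeros((4, 4))
        a[0, :4] = 1
        b = np.zeros((4, 4))
        b[0, 2:] = 1
        b[1, :2] = 1
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_is_zero(self):
        assert iou(np.zeros((3, 3)), np.zeros((3, 3))) == 0.0


class TestDiceCoefficient:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5))
        m[1:4, 1:4] = 1
        assert dice_coefficient(m, m) == 1.0

    def test_hand_count(self):
        a = np.zeros((4, 4))
        a[0, :4] = 1
        b = np.zeros((4, 4))
        b[0, 2:] = 1
        b[1, :2] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_one_sided_empty_is_zero(self):
        gt = np.zeros((3, 3))
        gt[1, 1] = 1
        assert dice_coefficient(gt, np.zeros((3, 3))) == 0.0

    def test_both_empty_is_one(self):
        assert dice_coefficient(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0


class TestAji:
    def test_perfect_prediction(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[1:3, 1:3] = 1
        lab[5:7, 5:7] = 2
        assert aji(lab, lab) == 1.0

    def test_empty_prediction_scores_zero(self):
        gt = np.zeros((6, 6), dtype=int)
        gt[2:4, 2:4] = 1
        assert aji(gt, np.zeros_like(gt)) == 0.0
        assert aji(np.zeros_like(gt), gt) == 0.0

    def test_shifted_square_hand_case(self):
        # 2x2 gt vs 2x2 pred shifted one column: inter 2, union 6
        gt = np.zeros((6, 6), dtype=int)
        gt[2:4, 2:4] = 1
        pred = np.zeros((6, 6), dtype=int)
        pred[2:4, 3:5] = 1
        assert aji(gt, pred) == pytest.approx(2 / 6)

    def test_single_use_of_predictions(self):
        # two gt squares both best-match the same prediction; the second gt
        # cannot reuse it and contributes only its own area
        gt = np.zeros((4, 10), dtype=int)
        gt[1:3, 1:3] = 1
        gt[1:3, 4:6] = 2
        pred = np.zeros((4, 10), dtype=int)
        pred[1:3, 1:6] = 1  # one blob covering both
        assert aji(gt, pred) == pytest.approx(brute_force_aji(gt, pred))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        gt = random_label_map(rng)
        pred = random_label_map(rng)
        relabeled = np.where(pred == 0, 0, (pred * 7) % 11 + 1)
        assert aji(gt, pred) == pytest.approx(aji(gt, canonicalize(relabeled)), abs=1e-12)


class TestPanopticQuality:
    def test_perfect_three_instances(self):
        lab = np.zeros((9, 9), dtype=int)
        lab[0:2, 0:2] = 1
        lab[4:6, 4:6] = 2
        lab[7:9, 7:9] = 3
        pq, table = panoptic_quality(lab, lab)
        assert pq == 1.0
        assert len(table.tp_pairs) == 3
        assert not table.fp_labels and not table.fn_labels

    def test_hand_case_one_tp_one_fp_one_fn(self):
        # TP with IoU 0.6 (3/5), plus one spurious pred and one missed gt
        gt = np.zeros((8, 12), dtype=int)
        gt[0, 0:5] = 1          # matched gt, area 5
        gt[4:6, 8:10] = 2       # missed gt
        pred = np.zeros((8, 12), dtype=int)
        pred[0, 0:3] = 1        # overlaps 3 of 5 -> IoU 3/5
        pred[7, 0:4] = 2        # spurious
        pq, table = panoptic_quality(gt, pred)
        assert pq == pytest.approx(0.6 / 2)
        assert len(table.tp_pairs) == 1
        assert len(table.fp_labels) == 1 and len(table.fn_labels) == 1

    def test_one_sided_empty_is_zero(self):
        gt = np.zeros((5, 5), dtype=int)
        gt[1:3, 1:3] = 1
        assert panoptic_quality(gt, np.zeros_like(gt))[0] == 0.0

    def test_both_empty_is_one(self):
        z = np.zeros((5, 5), dtype=int)
        assert panoptic_quality(z, z)[0] == 1.0

    def test_matching_uniqueness_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            gt, pred = random_label_map(rng), random_label_map(rng)
            _, table = panoptic_quality(gt, pred)
            gts = [g for g, _, _ in table.tp_pairs]
            preds = [p for _, p, _ in table.tp_pairs]
            assert len(gts) == len(set(gts))
            assert len(preds) == len(set(preds))
            assert all(v > 0.5 for _, _, v in table.tp_pairs)


class TestBruteForceEquivalence:
    def test_aji_and_pq_match_reference_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(500):
            gt, pred = random_label_map(rng), random_label_map(rng)
            assert aji(gt, pred) == pytest.approx(brute_force_aji(gt, pred), abs=1e-12)
            assert panoptic_quality(gt, pred)[0] == pytest.approx(
                brute_force_pq(gt, pred), abs=1e-12
            )

    def test_all_metrics_perfect_iff_identical_partition(self):
        rng = np.random.default_rng(5)
        gt = random_label_map(rng)
        while gt.max() < 2:
            gt = random_label_map(rng)
        shuffled = np.where(gt == 0, 0, gt % gt.max() + 1)
        assert aji(gt, shuffled) == 1.0
        assert panoptic_quality(gt, shuffled)[0] == 1.0
        assert dice_coefficient(gt > 0, shuffled > 0) == 1.0


class TestLabelPermutationInvariance:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16), mult=st.integers(2, 97))
    def test_metrics_invariant_under_relabeling(self, seed, mult):
        rng = np.random.default_rng(seed)
        gt, pred = random_label_map(rng), random_label_map(rng)
        # any injective relabeling of positive labels leaves the metrics fixed
        permuted = np.where(pred == 0, 0, pred * mult + 1)
        assert aji(gt, permuted) == pytest.approx(aji(gt, pred), abs=1e-12)
        assert panoptic_quality(gt, permuted)[0] == pytest.approx(
            panoptic_quality(gt, pred)[0], abs=1e-12
        )
        assert dice_coefficient(gt > 0, permuted > 0) == dice_coefficient(
            gt > 0, pred > 0
        )


class TestEvaluateBatch:
    def _pair(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[1:4, 1:4] = 1
        lab[5:7, 5:7] = 2
        return lab, lab

    def test_perfect_batch_means(self):
        df = evaluate_batch([self._pair(), self._pair()])
        mean = df[df["image_id"] == "mean"].iloc[0]
        assert (mean[["aji", "dice", "pq"]] == 1.0).all()

    def test_single_image_batch_matches_per_image_ops(self):
        gt, _ = self._pair()
        pred = np.roll(gt, 1, axis=1)
        df = evaluate_batch([(gt, pred)])
        row = df.iloc[0]
        assert row["aji"] == pytest.approx(aji(gt, pred))
        assert row["pq"] == pytest.approx(panoptic_quality(gt, pred)[0])
        assert row["dice"] == pytest.approx(dice_coefficient(gt > 0, pred > 0))

    def test_mean_row_is_arithmetic_average(self):
        rng = np.random.default_rng(2)
        pairs = [(random_label_map(rng), random_label_map(rng)) for _ in range(5)]
        df = evaluate_batch(pairs)
        body = df[df["image_id"] != "mean"]
        mean = df[df["image_id"] == "mean"].iloc[0]
        for col in ("aji", "dice", "pq"):
            assert mean[col] == pytest.approx(body[col].mean(), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_batch([])
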