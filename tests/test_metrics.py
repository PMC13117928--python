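import itertools

import numpy as np
import pytest

from masseg import (
    Box,
    DetectionSet,
    average_precision,
    dice,
    giou,
    hd95,
    iou,
    match,
    precision_recall,
    rank_sum_test,
    stratified_kfold,
)
from masseg.metrics import FoldScores, MatchResult

import oracles


class TestBoxOverlap:
    def test_identical_boxes(self):
        b = Box(3, 4, 13, 24)
        assert iou(b, b) == 1.0
        assert giou(b, b) == 1.0

    def test_one_third_overlap(self):
        a, b = Box(0, 0, 10, 10), Box(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(1 / 3)
        # enclosing box equals the union here, so GIoU == IoU
        assert giou(a, b) == pytest.approx(1 / 3)

    def test_disjoint_boxes(self):
        a, b = Box(0, 0, 10, 10), Box(20, 0, 30, 10)
        assert iou(a, b) == 0.0
        assert giou(a, b) == pytest.approx(-1 / 3)

    def test_giou_never_exceeds_iou(self, rng):
        for _ in range(100):
            x = rng.integers(0, 50, size=8)
            a = Box(x[0], x[1], x[0] + x[2] + 1, x[1] + x[3] + 1)
            b = Box(x[4], x[5], x[4] + x[6] + 1, x[5] + x[7] + 1)
            assert giou(a, b) <= iou(a, b) + 1e-12

    def test_iou_matches_pixel_enumeration(self, rng):
        for _ in range(100):
            x = rng.integers(0, 20, size=8)
            a = (x[0], x[1], x[0] + x[2] + 1, x[1] + x[3] + 1)
            b = (x[4], x[5], x[4] + x[6] + 1, x[5] + x[7] + 1)
            got = iou(Box(*a), Box(*b))
            assert got == pytest.approx(oracles.iou_sets(a, b), abs=1e-9)


class TestMatch:
    def test_single_true_positive(self):
        preds = [Box(0, 0, 10, 10, confidence=0.9)]
        gts = [Box(1, 0, 11, 10)]
        m = match(preds, gts, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_one_match_per_ground_truth(self):
        preds = [Box(0, 0, 10, 10, confidence=0.9),
                 Box(1, 0, 11, 10, confidence=0.8)]
        gts = [Box(0, 0, 10, 10)]
        m = match(preds, gts, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][0] == 0  # higher confidence claims the gt

    def test_all_missed(self):
        m = match([], [Box(0, 0, 5, 5), Box(10, 10, 15, 15)], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 2)

    def test_precision_recall_conventions(self):
        assert precision_recall(MatchResult(3, 1, 2, ((0, 0, 1.0),) * 3)) == (
            0.75, 0.6)
        assert precision_recall(MatchResult(0, 0, 2, ())) == (1.0, 0.0)
        assert precision_recall(MatchResult(2, 0, 0, ((0, 0, 1.0),) * 2)) == (
            1.0, 1.0)


class TestAveragePrecision:
    GT = Box(0, 0, 10, 10)
    HIT = Box(0, 0, 10, 10)      # IoU 1 with GT
    MISS = Box(40, 40, 50, 50)   # disjoint

    def test_single_true_positive_is_one(self):
        ap = average_precision({"a": [Box(0, 0, 10, 10, confidence=0.9)]},
                               {"a": [self.GT]}, 0.5)
        assert ap == 1.0

    def test_fp_before_tp_halves_ap(self):
        preds = [Box(40, 40, 50, 50, confidence=0.9),
                 Box(0, 0, 10, 10, confidence=0.8)]
        assert average_precision({"a": preds}, {"a": [self.GT]}, 0.5) == 0.5

    def test_tp_before_fp_keeps_ap_one(self):
        preds = [Box(0, 0, 10, 10, confidence=0.9),
                 Box(40, 40, 50, 50, confidence=0.8)]
        assert average_precision({"a": preds}, {"a": [self.GT]}, 0.5) == 1.0

    def test_zero_ground_truths_rejected(self):
        with pytest.raises(ValueError):
            average_precision({"a": []}, {"a": []}, 0.5)

    def test_matches_prefix_enumeration_on_all_toy_sets(self):
        """Exhaustive check against an independent prefix-PR computation for
        every TP/FP pattern of up to 6 predictions on a 3-gt image."""
        gts = [Box(0, 0, 10, 10), Box(20, 0, 30, 10), Box(40, 0, 50, 10)]
        for n in range(1, 7):
            for pattern in itertools.product([True, False], repeat=n):
                if sum(pattern) > len(gts):
                    continue
                preds = []
                hit_idx = 0
                for i, is_tp in enumerate(pattern):
                    conf = 0.95 - 0.1 * i
                    if is_tp:
                        g = gts[hit_idx]
                        preds.append(Box(g.x0, g.y0, g.x1, g.y1, confidence=conf))
                        hit_idx += 1
                    else:
                        preds.append(Box(60 + 11 * i, 40, 70 + 11 * i, 50,
                                         confidence=conf))
                got = average_precision({"a": preds}, {"a": gts}, 0.5)
                want = oracles.average_precision_prefixes(
                    [b.confidence for b in preds], list(pattern), len(gts)
                )
                assert got == pytest.approx(want, abs=1e-12)


class TestMaskMetrics:
    def test_dice_identical_and_disjoint(self, rng):
        m = rng.random((16, 16)) > 0.5
        assert dice(m, m) == 1.0
        a = np.zeros((8, 8), bool); a[:2, :2] = True
        b = np.zeros((8, 8), bool); b[6:, 6:] = True
        assert dice(a, b) == 0.0

    def test_dice_shifted_square(self):
        a = np.zeros((8, 8), bool); a[2:4, 2:4] = True
        b = np.zeros((8, 8), bool); b[2:4, 3:5] = True
        assert dice(a, b) == 0.5

    def test_hd95_identical_masks_zero(self, rng):
        m = np.zeros((16, 16), bool); m[4:10, 5:12] = True
        assert hd95(m, m) == 0.0

    def test_hd95_two_points(self):
        a = np.zeros((16, 16), bool); a[3, 3] = True
        b = np.zeros((16, 16), bool); b[3, 8] = True
        assert hd95(a, b) == 5.0

    def test_hd95_empty_mask_sentinel_is_diagonal(self):
        a = np.zeros((640, 640), bool)
        b = np.zeros((640, 640), bool); b[100:110, 100:110] = True
        assert hd95(a, b) == pytest.approx(640 * np.sqrt(2))
        assert hd95(a, a) == 0.0

    def test_symmetry_and_brute_force_agreement(self, rng):
        for _ in range(25):
            a = rng.random((12, 12)) > 0.6
            b = rng.random((12, 12)) > 0.6
            assert dice(a, b) == dice(b, a)
            assert dice(a, b) == pytest.approx(oracles.dice_sets(a, b), abs=1e-9)
            for mode in ("pooled", "max_directed"):
                got = hd95(a, b, mode=mode)
                assert got == pytest.approx(hd95(b, a, mode=mode), abs=1e-9)
                assert got == pytest.approx(
                    oracles.hd95_brute(a, b, mode=mode), abs=1e-9)


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_exact_small_sample_enumeration(self):
        # all C(4,2)=6 rank splits; the observed split is one extreme (1/6
        # per tail), two-sided doubles it
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_far_shift_is_significant(self):
        x = np.arange(10) + 100.0
        y = np.arange(10).astype(float)
        assert rank_sum_test(x, y) < 0.001

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestStratifiedKfold:
    def test_balanced_two_class_ten_folds(self):
        labels = ["a"] * 10 + ["b"] * 10
        folds = stratified_kfold(labels, 10, seed=0)
        for f in range(10):
            sel = folds == f
            assert sel.sum() == 2
            assert sum(1 for i in np.flatnonzero(sel) if labels[i] == "a") == 1

    def test_deterministic_under_seed(self):
        labels = ["a"] * 13 + ["b"] * 10
        f1 = stratified_kfold(labels, 10, seed=7)
        f2 = stratified_kfold(labels, 10, seed=7)
        np.testing.assert_array_equal(f1, f2)

    def test_unbalanced_counts_within_one_of_proportional(self):
        labels = ["a"] * 13 + ["b"] * 10
        folds = stratified_kfold(labels, 10, seed=3)
        sizes = [int((folds == f).sum()) for f in range(10)]
        assert set(sizes) <= {2, 3}
        for f in range(10):
            idx = np.flatnonzero(folds == f)
            for cls, n_cls in (("a", 13), ("b", 10)):
                n = sum(1 for i in idx if labels[i] == cls)
                assert abs(n - n_cls / 10) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a", "b"], 3, seed=0)


class TestFoldScores:
    def test_mean_sd_recomputable(self, rng):
        vals = rng.random(10)
        fs = FoldScores.from_values("m", vals)
        assert fs.mean == pytest.approx(np.mean(vals), abs=1e-12)
        assert fs.sd == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
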