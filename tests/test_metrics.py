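"""Evaluation metrics: confusion tallies, ratio metrics, HD95 and its
agreement with brute-force and distance-transform references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import distance_transform_edt

from _reference import hd95_ref
from mambaseg.losses import weighted_dice_loss
from mambaseg.metrics import (ConfusionCounts, boundary_points, confusion,
                              dice_precision_recall, evaluate_dataset,
                              evaluate_pair, hd95, write_metrics_csv)


class TestConfusion:
    def test_identical_and_complementary(self, rng):
        m = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = confusion(m, m)
        assert c.FP == c.FN == 0 and c.TP == m.sum()
        c2 = confusion(m, 1 - m)
        assert c2.TP == c2.TN == 0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(0, 2, (3, 3))
        g = rng.integers(0, 2, (3, 3))
        c = confusion(p, g)
        tally = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
        for i in range(3):
            for j in range(3):
                key = {(1, 1): "TP", (1, 0): "FP",
                       (0, 1): "FN", (0, 0): "TN"}[(p[i, j], g[i, j])]
                tally[key] += 1
        assert (c.TP, c.FP, c.FN, c.TN) == tuple(tally.values())
        assert c.total == 9

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            confusion(np.array([[0, 2]]), np.array([[0, 1]]))


class TestRatios:
    def test_worked_example(self):
        d, p, r = dice_precision_recall(ConfusionCounts(8, 2, 2, 4))
        assert (d, p, r) == (0.8, 0.8, 0.8)

    def test_perfect_and_degenerate(self):
        assert dice_precision_recall(ConfusionCounts(5, 0, 0, 4)) == (1, 1, 1)
        assert dice_precision_recall(ConfusionCounts(0, 3, 2, 4))[0] == 0
        # both masks empty → all ones by convention
        assert dice_precision_recall(ConfusionCounts(0, 0, 0, 9)) == (1, 1, 1)

    def test_dice_equals_one_minus_dice_loss_on_hard_masks(self, rng):
        pred = (rng.random((8, 8)) > 0.6).astype(float)
        true = (rng.random((8, 8)) > 0.6).astype(float)
        d = dice_precision_recall(confusion(pred, true))[0]
        # soft Dice on one foreground class, weight concentrated there
        loss = weighted_dice_loss(pred.reshape(1, -1), true.reshape(1, -1),
                                  (1.0,))
        np.testing.assert_allclose(d, 1 - loss, atol=1e-5)


class TestHD95:
    def test_identical_sets_zero(self):
        pts = np.array([[0, 0], [1, 2], [3, 3]])
        assert hd95(pts, pts) == 0.0

    def test_singleton_euclidean(self):
        assert hd95([[0, 0]], [[3, 4]]) == pytest.approx(5.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hd95(np.empty((0, 2)), [[1, 1]])

    def test_spacing_scales_linearly(self):
        a, b = [[0, 0]], [[0, 2]]
        assert hd95(a, b, spacing=0.7) == pytest.approx(1.4)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_brute_force_agreement(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.integers(0, 10, (5, 2))
        B = rng.integers(0, 10, (5, 2))
        got = hd95(A, B)
        assert got == pytest.approx(hd95(B, A))
        assert got == pytest.approx(hd95_ref(A, B), rel=1e-9)
        # never exceeds the exact symmetric Hausdorff distance
        d = np.sqrt(((A[:, None] - B[None]) ** 2).sum(-1))
        exact = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert got <= exact + 1e-9


class TestBoundaryAndPairs:
    def test_boundary_of_solid_square(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 1
        pts = {tuple(p) for p in boundary_points(m)}
        assert (3, 3) not in pts          # interior eroded away
        assert (2, 2) in pts and (4, 4) in pts
        assert len(pts) == 8

    def test_evaluate_pair_perfect(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 3:6] = 1
        r = evaluate_pair(m, m)
        assert r["dice"] == 1.0 and r["hd95"] == 0.0

    def test_evaluate_pair_empty_prediction(self):
        g = np.zeros((8, 8), dtype=np.uint8)
        g[2:4, 2:4] = 1
        r = evaluate_pair(np.zeros_like(g), g)
        assert r["dice"] == 0.0 and np.isnan(r["hd95"])

    def test_distance_transform_reference(self, rng):
        """KD-tree HD95 equals the distance-transform formulation used by
        standard medical-imaging metric implementations."""
        a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        pa, pb = boundary_points(a), boundary_points(b)
        bd_a = np.zeros_like(a, dtype=bool)
        bd_a[tuple(pa.T)] = True
        bd_b = np.zeros_like(b, dtype=bool)
        bd_b[tuple(pb.T)] = True
        dt_b = distance_transform_edt(~bd_b)
        dt_a = distance_transform_edt(~bd_a)
        ref = max(np.percentile(dt_b[bd_a], 95), np.percentile(dt_a[bd_b], 95))
        assert hd95(pa, pb) == pytest.approx(ref, abs=1e-9)

    def test_dataset_aggregate_and_csv(self, tmp_path, rng):
        masks = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(4)]
        rows, agg = evaluate_dataset([(m, m) for m in masks])
        assert agg["dice"] == 1.0 and agg["hd95"] == 0.0
        out = tmp_path / "m.csv"
        write_metrics_csv(out, rows, agg)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 6 and lines[-1].startswith("mean")
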