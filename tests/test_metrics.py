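import numpy as np
import pandas as pd
import pytest

from histolink.metrics import (
    MatchResult,
    binary_overlap,
    brute_force_instance_match,
    cell_quality_scores,
    detection_prf,
    filter_patches,
    match_instances,
    matched_confusion,
    panoptic,
    per_class_panoptic,
)


def blob(size, r0, c0, h, w, value=1):
    m = np.zeros((size, size), dtype=np.int32)
    m[r0:r0 + h, c0:c0 + w] = value
    return m


class TestBinaryOverlap:
    def test_identical_masks(self):
        a = blob(16, 2, 2, 4, 4) > 0
        assert binary_overlap(a, a) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = blob(16, 0, 0, 4, 4) > 0
        b = blob(16, 8, 8, 4, 4) > 0
        assert binary_overlap(a, b) == (0.0, 0.0)

    def test_counted_overlap(self):
        # two 4x4 squares overlapping on 12 px (union 20)
        a = blob(16, 0, 0, 4, 4) > 0
        b = blob(16, 1, 0, 4, 4) > 0
        dice, jac = binary_overlap(a, b)
        assert dice == pytest.approx(0.75)
        assert jac == pytest.approx(0.6)

    def test_both_empty_score_one(self):
        z = np.zeros((8, 8), dtype=bool)
        assert binary_overlap(z, z) == (1.0, 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_overlap(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_dice_jaccard_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.uniform(size=(32, 32)) < rng.uniform(0.05, 0.6)
            b = rng.uniform(size=(32, 32)) < rng.uniform(0.05, 0.6)
            dice, jac = binary_overlap(a, b)
            assert abs(dice - 2 * jac / (1 + jac)) < 1e-12


class TestMatchInstances:
    def test_identical_maps_all_tp_at_unit_iou(self):
        m = blob(32, 2, 2, 5, 5, 1) + blob(32, 20, 20, 6, 6, 2)
        res = match_instances(m, m)
        assert res.n_tp == 2 and not res.fp and not res.fn
        assert all(iou == 1.0 for *_, iou in res.tp)

    def test_empty_prediction_all_fn(self):
        m = blob(32, 2, 2, 5, 5, 1) + blob(32, 20, 20, 6, 6, 2)
        res = match_instances(m, np.zeros_like(m))
        assert res.n_tp == 0 and res.fn == [1, 2] and res.fp == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        """Hungarian matching attains the brute-force optimum of summed IoU."""
        rng = np.random.default_rng(seed)
        gt = np.zeros((48, 48), dtype=np.int32)
        pred = np.zeros((48, 48), dtype=np.int32)
        for i in range(3):
            r, c = 4 + 14 * i, 4 + 10 * i
            gt[r:r + 7, c:c + 7] = i + 1
            dr, dc = rng.integers(-2, 3, size=2)
            pred[r + dr:r + dr + 7, c + dc:c + dc + 7] = i + 1
        res = match_instances(gt, pred, iou_threshold=0.2)
        achieved = sum(iou for *_, iou in res.tp)
        best = brute_force_instance_match(gt, pred, iou_threshold=0.2)
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_invariant_under_id_relabeling(self):
        gt = blob(32, 2, 2, 5, 5, 1) + blob(32, 20, 20, 6, 6, 2)
        pred = blob(32, 2, 2, 5, 5, 7) + blob(32, 20, 20, 6, 6, 3)
        res = match_instances(gt, pred)
        assert panoptic(res) == (1.0, 1.0, 1.0)


class TestPanoptic:
    def test_identity(self):
        m = blob(32, 2, 2, 5, 5, 1)
        assert panoptic(match_instances(m, m)) == (1.0, 1.0, 1.0)

    def test_single_tp_sq(self):
        res = MatchResult(tp=[(1, 1, 0.6)], fp=[], fn=[])
        assert panoptic(res) == pytest.approx((1.0, 0.6, 0.6))

    def test_tp_fp_fn_arithmetic(self):
        res = MatchResult(tp=[(1, 1, 0.8)], fp=[2], fn=[3])
        dq, sq, pq = panoptic(res)
        assert dq == pytest.approx(0.5)
        assert pq == pytest.approx(0.4)
        assert pq == pytest.approx(dq * sq)

    def test_empty_vs_empty_convention(self):
        assert panoptic(MatchResult([], [], [])) == (1.0, 1.0, 1.0)


class TestPerClassPanoptic:
    def test_single_category_identity(self):
        inst = blob(32, 2, 2, 5, 5, 1)
        types = (inst > 0).astype(np.int32) * 3
        per, mpq = per_class_panoptic(inst, types, inst, types)
        assert per[3] == (1.0, 1.0, 1.0)
        assert mpq == 1.0

    def test_missed_category_contributes_zero(self):
        gt_inst = blob(32, 2, 2, 5, 5, 1) + blob(32, 20, 20, 5, 5, 2)
        gt_types = np.where(gt_inst == 1, 1, 0) + np.where(gt_inst == 2, 2, 0)
        pred_inst = blob(32, 2, 2, 5, 5, 1)
        pred_types = (pred_inst > 0).astype(np.int32)
        per, mpq = per_class_panoptic(gt_inst, gt_types, pred_inst, pred_types)
        assert per[1] == (1.0, 1.0, 1.0)
        assert per[2][2] == 0.0
        assert mpq == pytest.approx(0.5)

    def test_two_category_toy_equals_manual(self):
        gt_inst = blob(32, 2, 2, 4, 4, 1) + blob(32, 20, 2, 4, 4, 2)
        gt_types = np.where(gt_inst == 1, 1, 0) + np.where(gt_inst == 2, 2, 0)
        pred_inst = blob(32, 2, 2, 4, 4, 1) + blob(32, 21, 2, 4, 4, 2)  # cat2 shifted 1 row
        pred_types = np.where(pred_inst == 1, 1, 0) + np.where(pred_inst == 2, 2, 0)
        per, mpq = per_class_panoptic(gt_inst, gt_types, pred_inst, pred_types)
        assert per[1] == (1.0, 1.0, 1.0)
        iou = 12 / 20  # 3x4 overlap over union 20
        assert per[2] == pytest.approx((1.0, iou, iou))
        assert mpq == pytest.approx((1.0 + iou) / 2)


class TestDetection:
    def test_perfect(self):
        assert detection_prf(MatchResult([(1, 1, 1.0)], [], [])) == (1.0, 1.0, 1.0)

    def test_arithmetic(self):
        p, r, f1 = detection_prf(MatchResult([(1, 1, 0.9)], [2], []))
        assert (p, r) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_no_predictions(self):
        assert detection_prf(MatchResult([], [], [1, 2])) == (0.0, 0.0, 0.0)


class TestMatchedConfusion:
    def test_identity_types(self):
        match = MatchResult([(1, 1, 1.0), (2, 2, 1.0)], [], [])
        mat = matched_confusion({1: 1, 2: 2}, {1: 1, 2: 2}, match, 2)
        assert np.allclose(mat[:, :2], np.eye(2))
        assert mat[:, 2].sum() == 0

    def test_half_reassigned_row(self):
        match = MatchResult([(1, 1, 1.0), (2, 2, 1.0)], [], [])
        mat = matched_confusion({1: 1, 2: 1}, {1: 1, 2: 2}, match, 2)
        assert mat[0, 0] == pytest.approx(0.5)
        assert mat[0, 1] == pytest.approx(0.5)

    def test_fn_only_category_mass_in_background(self):
        match = MatchResult([], [], [5])
        mat = matched_confusion({5: 2}, {}, match, 2)
        assert mat[1, 2] == 1.0
        sums = mat.sum(axis=1)
        assert sums[1] == pytest.approx(1.0)


class TestFilters:
    @pytest.fixture()
    def overview(self):
        return pd.DataFrame({
            "slide_id": ["s0"] * 10,
            "file_name": [f"s0_{i}" for i in range(10)],
            "Jaccard": [0.1, 0.2, 0.3, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9],
            "Epithelial": [1] * 10,
            "T_NK": [2] * 10,
        })

    def test_zero_threshold_keeps_everything(self, overview):
        out = filter_patches(overview, thresholds=[0.0])
        assert out.loc[0, "retained_patches"] == 10
        assert out.loc[0, "retained_instances"] == 30

    def test_threshold_one_strict_drops_everything(self, overview):
        out = filter_patches(overview, thresholds=[1.0])
        assert out.loc[0, "retained_patches"] == 0

    def test_manual_count_at_candidate_cutoffs(self, overview):
        out = filter_patches(overview, thresholds=[0.35, 0.45, 0.55])
        assert out["retained_patches"].tolist() == [7, 5, 4]
        assert out.loc[1, "retained_instances"] == 15

    def test_missing_metric_column_rejected(self, overview):
        with pytest.raises(KeyError):
            filter_patches(overview, metric="bPQ_missing")


class TestCellQuality:
    def test_single_patch_score_passthrough(self):
        s = cell_quality_scores({"c": [0]}, {0: 0.7})
        assert s["c"] == pytest.approx(0.7)

    def test_mean_over_patches_and_cutoff(self):
        s = cell_quality_scores({"a": [0, 1], "b": [2]}, {0: 0.4, 1: 0.8, 2: 0.1})
        assert s["a"] == pytest.approx(0.6)
        kept = s[s >= 0.2]
        assert "b" not in kept.index

    def test_orphan_cell_rejected(self):
        with pytest.raises(ValueError):
            cell_quality_scores({"a": []}, {})
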