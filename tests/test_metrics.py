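import numpy as np
import pytest

from _oracles import oracle_miou
from plateseg.metrics import (
    approximate_cell_mask,
    confusion_matrix,
    evaluate,
    iou,
    miou,
    pairwise_report,
    volume_fractions,
)
from plateseg.volume_io import LabelVolume


class TestIoU:
    def test_basic_values(self):
        a = np.array([1, 1, 1, 0], dtype=bool)
        b = np.array([1, 1, 0, 1], dtype=bool)
        assert iou(a, a) == 1.0
        assert iou(a, ~a) == 0.0
        assert iou(a, b) == pytest.approx(0.5)

    def test_both_empty_is_nan(self):
        z = np.zeros(5, dtype=bool)
        assert np.isnan(iou(z, z))


class TestMIoU:
    def test_perfect_prediction(self, rng):
        lab = rng.integers(0, 7, size=(3, 6, 6)).astype(np.uint8)
        assert miou(lab, lab) == 1.0

    def test_absent_classes_excluded_from_mean(self):
        truth = np.zeros((1, 4, 6), dtype=np.uint8)
        pred = np.zeros((1, 4, 6), dtype=np.uint8)
        truth[0, :, 0] = 2
        pred[0, :, 0] = 2  # class 2 agrees
        truth[0, :, 1] = 3
        pred[0, :, 1] = 3  # class 3 agrees
        truth[0, :, 2] = 4
        pred[0, :, 3] = 4  # class 4 disjoint; 5, 6 absent from both
        assert miou(truth, pred, (2, 3, 4, 5, 6)) == pytest.approx(2 / 3)

    def test_strict_empty_mode_scores_one(self):
        truth = np.full((1, 2, 2), 2, dtype=np.uint8)
        pred = truth.copy()
        assert miou(truth, pred, (2, 3, 4, 5, 6), strict_empty=True) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_set_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 7, size=(4, 10, 10)).astype(np.uint8)
        pred = rng.integers(0, 7, size=(4, 10, 10)).astype(np.uint8)
        mask = rng.random(truth.shape) < 0.7
        for classes in ((0, 1, 2, 3, 4, 5, 6), (2, 3, 4, 5, 6), (1,)):
            assert miou(truth, pred, classes) == pytest.approx(
                oracle_miou(truth, pred, classes), abs=1e-9
            )
            assert miou(truth, pred, classes, mask) == pytest.approx(
                oracle_miou(truth, pred, classes, mask), abs=1e-9
            )

    def test_symmetry(self, rng):
        a = rng.integers(0, 7, size=(3, 8, 8)).astype(np.uint8)
        b = rng.integers(0, 7, size=(3, 8, 8)).astype(np.uint8)
        assert miou(a, b) == pytest.approx(miou(b, a))

    def test_empty_subset_rejected(self, rng):
        lab = rng.integers(0, 2, size=(2, 4, 4)).astype(np.uint8)
        with pytest.raises(ValueError):
            miou(lab, lab, ())


class TestConfusion:
    def test_diagonal_for_perfect_prediction(self, rng):
        lab = rng.integers(0, 7, size=(3, 8, 8)).astype(np.uint8)
        cm = confusion_matrix(lab, lab)
        assert np.all(cm == np.diag(np.bincount(lab.ravel(), minlength=7)))

    def test_marginals_conserve_class_counts(self, rng):
        t = rng.integers(0, 7, size=(3, 8, 8)).astype(np.uint8)
        p = rng.integers(0, 7, size=(3, 8, 8)).astype(np.uint8)
        cm = confusion_matrix(t, p)
        np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(t.ravel(), minlength=7))
        np.testing.assert_array_equal(cm.sum(axis=0), np.bincount(p.ravel(), minlength=7))
        assert cm.sum() == t.size

    def test_single_off_diagonal_entry(self):
        t = np.full((1, 2, 2), 1, dtype=np.uint8)
        p = np.full((1, 2, 2), 4, dtype=np.uint8)
        cm = confusion_matrix(t, p)
        assert cm[1, 4] == 4 and cm.sum() == 4

    def test_diagonal_ious_recover_miou(self, rng):
        # cross-check identity: per-class IoU from confusion marginals
        t = rng.integers(0, 7, size=(4, 8, 8)).astype(np.uint8)
        p = rng.integers(0, 7, size=(4, 8, 8)).astype(np.uint8)
        cm = confusion_matrix(t, p)
        ious = []
        for j in range(7):
            union = cm[j].sum() + cm[:, j].sum() - cm[j, j]
            if union:
                ious.append(cm[j, j] / union)
        assert miou(t, p) == pytest.approx(np.mean(ious))


class TestVolumeFractions:
    def test_simple_fractions(self):
        lab = np.zeros((1, 10, 100), dtype=np.uint8)
        mask = np.zeros_like(lab, dtype=bool)
        mask[0, :, :] = True  # 1000 voxels
        lab[0, 0, :60] = 4
        lab[0, 1, :40] = 2
        fr = volume_fractions(lab, mask)
        assert fr[4] == pytest.approx(0.06)
        assert fr[2] == pytest.approx(0.04)
        assert fr[3] == fr[5] == fr[6] == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            volume_fractions(np.zeros((1, 2, 2), np.uint8), np.zeros((1, 2, 2), bool))

    def test_pure_organelle_mask(self):
        lab = np.full((1, 3, 3), 5, dtype=np.uint8)
        fr = volume_fractions(lab, np.ones_like(lab, dtype=bool))
        assert fr[5] == 1.0


class TestCellMask:
    def test_radius_zero_intersects(self):
        seg = np.zeros((3, 5, 5), dtype=np.uint8)
        seg[1, 2, 2] = 1
        ref = np.ones_like(seg, dtype=bool)
        out = approximate_cell_mask(seg, ref, 0)
        assert out.sum() == 1 and out[1, 2, 2]

    def test_background_segmentation_gives_empty_mask(self):
        seg = np.zeros((3, 5, 5), dtype=np.uint8)
        assert approximate_cell_mask(seg, np.ones((3, 5, 5), bool), 2).sum() == 0

    def test_monotone_in_radius(self, rng):
        seg = (rng.random((4, 8, 8)) < 0.6).astype(np.uint8)
        ref = np.zeros((4, 8, 8), bool)
        ref[2, 4, 4] = True
        m1 = approximate_cell_mask(seg, ref, 1)
        m2 = approximate_cell_mask(seg, ref, 3)
        assert np.all(m2[m1])


class TestPairwise:
    def test_identical_segmentations(self, rng):
        lab = rng.integers(0, 7, size=(2, 6, 6)).astype(np.uint8)
        names, mat, conf = pairwise_report({"a": lab, "b": lab.copy()})
        np.testing.assert_allclose(mat, 1.0)

    def test_symmetry_and_consistency_with_miou(self, rng):
        segs = {
            n: rng.integers(0, 7, size=(2, 6, 6)).astype(np.uint8)
            for n in ("ann1", "ann2", "algo")
        }
        names, mat, conf = pairwise_report(segs)
        np.testing.assert_allclose(mat, mat.T)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert mat[i, j] == pytest.approx(
                        miou(segs[a], segs[b], (2, 3, 4, 5, 6))
                    )

    def test_requires_two_inputs(self, rng):
        with pytest.raises(ValueError):
            pairwise_report({"only": rng.integers(0, 7, size=(2, 4, 4))})


def test_evaluate_bundles_consistent_numbers(rng):
    t = LabelVolume(rng.integers(0, 7, size=(3, 8, 8)))
    p = LabelVolume(rng.integers(0, 7, size=(3, 8, 8)))
    rep = evaluate(t, p)
    assert rep.miou_all == pytest.approx(miou(t, p))
    assert rep.confusion.sum() == t.data.size
    assert len(rep.per_class_iou) == 7
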