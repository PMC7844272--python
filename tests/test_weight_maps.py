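import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import gaussian_kernel_1d, oracle_edge_slice, oracle_weight_volume
from plateseg.volume_io import LabelVolume
from plateseg.weight_maps import (
    EdgeWeightParams,
    build_weight_volume,
    class_balance_weights,
    diffusion_mask,
    directed_edge_weight,
    edge_preserving_slice,
    rectified_rescale,
)


def _labels(arr):
    return LabelVolume(np.asarray(arr, dtype=np.uint8))


class TestClassBalance:
    def test_two_class_inverse_frequency(self):
        lab = np.zeros((1, 10, 100), dtype=np.uint8)
        lab[:, :, :10] = 1  # 100 cell voxels vs 900 background
        w = class_balance_weights(_labels(lab))
        np.testing.assert_allclose(w, [1 / 9, 1, 0, 0, 0, 0, 0])

    def test_equal_counts_give_all_ones(self):
        lab = np.repeat(np.arange(7, dtype=np.uint8), 4).reshape(1, 7, 4)
        np.testing.assert_allclose(class_balance_weights(_labels(lab)), np.ones(7))

    def test_three_class_mixture(self):
        lab = np.concatenate(
            [np.zeros(500), np.full(250, 2), np.full(250, 4)]
        ).astype(np.uint8).reshape(1, 10, 100)
        w = class_balance_weights(_labels(lab))
        np.testing.assert_allclose(w, [0.5, 0, 1, 0, 1, 0, 0])

    def test_single_class_volume_gets_weight_one(self):
        w = class_balance_weights(_labels(np.ones((2, 3, 3))))
        assert w[1] == 1.0 and w.sum() == 1.0


class TestDiffusionMask:
    def test_zero_and_saturated_masks(self):
        zero = diffusion_mask(np.zeros((9, 9)), 0.882, 2.0)
        np.testing.assert_allclose(zero, 0.0)
        ones = diffusion_mask(np.ones((9, 9)), 0.882, 2.0)
        np.testing.assert_allclose(ones, 0.882, atol=1e-10)

    def test_centre_pixel_equals_kernel_peak(self):
        sigma, c = 3.0, 0.882
        slice_ = np.zeros((31, 31))
        slice_[15, 15] = 1.0
        out = diffusion_mask(slice_, c, sigma)
        k1 = gaussian_kernel_1d(sigma)
        expected = c * k1[len(k1) // 2] ** 2
        assert out[15, 15] == pytest.approx(expected, rel=1e-9)

    def test_rejects_non_binary_input(self):
        with pytest.raises(ValueError):
            diffusion_mask(np.full((4, 4), 0.5), 1.0, 1.0)


class TestDirectedEdgeWeight:
    def test_empty_source_or_target_is_zero(self):
        params = EdgeWeightParams(sigma=2.0)
        all_cell = np.ones((8, 8), dtype=np.uint8)
        out = directed_edge_weight(all_cell, {0}, {1}, params)
        np.testing.assert_allclose(out, 0.0)  # no background source anywhere
        all_bkgd = np.zeros((8, 8), dtype=np.uint8)
        out = directed_edge_weight(all_bkgd, {0}, {1}, params)
        np.testing.assert_allclose(out, 0.0)  # no cell target anywhere

    def test_rejects_overlapping_subsets(self):
        with pytest.raises(ValueError):
            directed_edge_weight(np.zeros((4, 4), np.uint8), {0, 1}, {1}, EdgeWeightParams())

    def test_half_plane_boundary_decay_matches_oracle(self):
        lab = np.zeros((21, 21), dtype=np.uint8)
        lab[:, 10:] = 1
        params = EdgeWeightParams(sigma=3.0)
        out = directed_edge_weight(lab, {0}, {1}, params)
        assert np.all(out[:, :10] == 0)
        col = out[10, 10:]
        assert np.all(np.diff(col) < 0)  # decays away from the boundary
        from _oracles import direct_gaussian_blur

        oracle = params.scale_c * direct_gaussian_blur((lab == 0).astype(float), 3.0)
        oracle[lab == 0] = 0.0
        np.testing.assert_allclose(out, oracle, atol=1e-6)


class TestRectifiedRescale:
    def test_printed_example(self):
        w = np.array([[1.0, 0.625, 0.25, 0.1]])
        out = rectified_rescale(w, 0.25)
        np.testing.assert_allclose(out, [[1.0, 0.5, 0.0, 0.0]])

    def test_degenerate_max_returns_zeros(self):
        np.testing.assert_allclose(rectified_rescale(np.full((3, 3), 0.2), 0.25), 0.0)

    @given(st.floats(0.0, 0.4), st.integers(0, 2**31 - 1))
    def test_maximum_maps_to_itself(self, alpha, seed):
        w = np.random.default_rng(seed).uniform(0, 1, size=(6, 6))
        out = rectified_rescale(w, alpha)
        if w.max() > alpha:
            assert out.max() == pytest.approx(w.max())
        assert np.all(out[w <= alpha] == 0)


class TestEdgePreservingSlice:
    def test_uniform_slices_are_zero(self):
        for fill in (0, 1):
            out = edge_preserving_slice(np.full((12, 12), fill, dtype=np.uint8))
            np.testing.assert_allclose(out, 0.0)

    def test_nested_blob_matches_oracle(self):
        lab = np.zeros((21, 21), dtype=np.uint8)
        lab[4:17, 4:17] = 1
        lab[9:13, 9:13] = 4
        params = EdgeWeightParams(sigma=2.0)
        out = edge_preserving_slice(lab, params)
        oracle = oracle_edge_slice(lab, params.floor_w, params.alpha,
                                   params.scale_c, params.sigma)
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_translation_equivariance_in_interior(self):
        rng = np.random.default_rng(0)
        lab = np.zeros((48, 48), dtype=np.uint8)
        lab[20:28, 20:26] = 1
        lab[22:25, 22:24] = 2
        params = EdgeWeightParams(sigma=1.5)
        base = edge_preserving_slice(lab, params)
        shifted = np.roll(lab, (3, -2), axis=(0, 1))
        out = edge_preserving_slice(shifted, params)
        np.testing.assert_allclose(
            out[10:38, 10:38], np.roll(base, (3, -2), axis=(0, 1))[10:38, 10:38],
            atol=1e-6,
        )

    def test_organelle_voxels_raise_nearby_cell_weight(self):
        # monotonicity: adding organelle voxels adjacent to cell voxels never
        # decreases the pre-rectification sum at nearby cell voxels
        params = EdgeWeightParams(sigma=2.0)
        lab = np.zeros((21, 21), dtype=np.uint8)
        lab[2:19, 2:19] = 1

        def pre_rect(lab):
            total = np.zeros(lab.shape)
            for s, t in ((frozenset({0}), frozenset({1})),
                         (frozenset({1}), frozenset({0})),
                         (frozenset({1}), frozenset({2, 3, 4, 5, 6})),
                         (frozenset({2, 3, 4, 5, 6}), frozenset({1}))):
                total += directed_edge_weight(lab, s, t, params)
            return total

        before = pre_rect(lab)
        lab2 = lab.copy()
        lab2[9:12, 9:12] = 4
        after = pre_rect(lab2)
        cell = lab2 == 1
        assert np.all(after[cell] >= before[cell] - 1e-12)


class TestBuildWeightVolume:
    def test_single_class_volume_is_floor_plus_one(self):
        wv = build_weight_volume(_labels(np.ones((2, 8, 8))))
        np.testing.assert_allclose(wv.data, 1.01)

    def test_all_background_slice_gets_floor_plus_cb(self):
        lab = np.zeros((2, 16, 16), dtype=np.uint8)
        lab[1, 4:12, 4:12] = 1  # slice 0 stays pure background
        params = EdgeWeightParams(sigma=2.0)
        wv = build_weight_volume(_labels(lab), params)
        cb = class_balance_weights(_labels(lab))
        np.testing.assert_allclose(wv.data[0], params.floor_w + cb[0])

    @pytest.mark.parametrize("seed", range(4))
    def test_random_phantom_slices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.zeros((3, 24, 24), dtype=np.uint8)
        for z in range(3):
            lab[z, 4:20, 4:20] = 1
            cy, cx = rng.integers(8, 16, size=2)
            lab[z, cy - 2 : cy + 2, cx - 2 : cx + 2] = rng.integers(2, 7)
        params = EdgeWeightParams(sigma=2.0)
        wv = build_weight_volume(_labels(lab), params)
        oracle = oracle_weight_volume(lab, params.floor_w, params.alpha,
                                      params.scale_c, params.sigma)
        np.testing.assert_allclose(wv.data, oracle, atol=1e-6)
        assert wv.data.min() >= params.floor_w
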