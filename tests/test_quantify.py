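"""Measurement operator contracts: means, projections, pair asymmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionoquant import synthetic as syn
from ionoquant.quantify import (brightest_substack_projection,
                                cell_mean_intensities, max_projection,
                                pair_asymmetry, roi_mean,
                                rolling_ball_subtract, tophat_bg_subtract)
from ionoquant.segmentation import segment_cells

from oracles import tophat_bruteforce


class TestTophatBgSubtract:
    def test_constant_channel_zeroed(self):
        out = tophat_bg_subtract(np.full((4, 32, 32), 300.0))
        assert np.allclose(out, 0.0)

    def test_matches_bruteforce_opening_residual(self, rng):
        zz, yy, xx = np.mgrid[:4, :32, :32]
        img = 3.0 * yy + 1.0 * xx + 0.0 * zz
        img[1:3, 10:16, 10:16] += 800.0
        out = tophat_bg_subtract(img, footprint_yxz=(15, 15, 1))
        oracle = tophat_bruteforce(img, (1, 15, 15))
        assert np.allclose(out, oracle, rtol=1e-5, atol=1e-8)


class TestCellMeans:
    def test_constant_channel_gives_constant_mean(self, fused_pair_spec):
        stack, _ = syn.generate_stack(fused_pair_spec, seed=0)
        seg = segment_cells(stack)
        const = np.full(stack.shape_zyx, 42.0)
        for m in cell_mean_intensities(seg, {"c": const}):
            assert m.mean_intensity["c"] == pytest.approx(42.0)
            assert m.n_voxels > 0

    def test_noiseless_means_within_5pct_of_truth(self):
        spec = syn.scatter_scene_spec(3, seed=4, poisson_scale=0.0,
                                      gaussian_sd=0.0)
        stack, truth = syn.generate_stack(spec, seed=4)
        seg = segment_cells(stack)
        sub = tophat_bg_subtract(stack.channel(1).astype(float))
        meas = {m.cell_id: m for m in cell_mean_intensities(seg, {"m": sub})}
        # match each predicted label to the truth label it overlaps most
        for cell_id, m in meas.items():
            sel = seg.labels == cell_id
            overlap = [(np.sum(sel & (truth.instance_labels == t)), t)
                       for t in truth.centroids]
            true_lab = max(overlap)[1]
            expected = truth.true_means[true_lab][1]
            assert m.mean_intensity["m"] == pytest.approx(expected, rel=0.05)

    def test_missing_label_errors(self, single_cell_spec):
        stack, _ = syn.generate_stack(single_cell_spec, seed=0)
        seg = segment_cells(stack)
        with pytest.raises(ValueError, match="absent"):
            cell_mean_intensities(seg, {"c": np.zeros(stack.shape_zyx)},
                                  required_labels=[99])

    def test_shape_mismatch_errors(self, single_cell_spec):
        stack, _ = syn.generate_stack(single_cell_spec, seed=0)
        seg = segment_cells(stack)
        with pytest.raises(ValueError, match="shape"):
            cell_mean_intensities(seg, {"c": np.zeros((2, 2, 2))})

    def test_untouched_second_channel_invariance(self, single_cell_spec):
        stack, _ = syn.generate_stack(single_cell_spec, seed=0)
        seg = segment_cells(stack)
        ch = stack.channel(0).astype(float)
        only = cell_mean_intensities(seg, {"a": ch})
        both = cell_mean_intensities(seg, {"a": ch, "b": np.zeros_like(ch)})
        assert [m.mean_intensity["a"] for m in only] == \
            [m.mean_intensity["a"] for m in both]


class TestProjections:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        assert np.array_equal(max_projection(img), img[0])

    def test_matches_elementwise_max(self, rng):
        stack = rng.uniform(0, 100, (8, 8, 8))
        oracle = np.maximum.reduce([stack[z] for z in range(8)])
        assert np.array_equal(max_projection(stack), oracle)

    def test_brightest_single_slice(self):
        stack = np.zeros((5, 4, 4))
        stack[3] = 7.0
        assert np.array_equal(brightest_substack_projection(stack, k=1),
                              stack[3])

    def test_k3_equals_max_projection_for_3_slices(self, rng):
        stack = rng.uniform(0, 10, (3, 6, 6))
        assert np.array_equal(brightest_substack_projection(stack, k=3),
                              max_projection(stack))

    def test_ranking_matches_sorted_slice_sums(self, rng):
        stack = rng.uniform(0, 10, (7, 5, 5))
        sums = [stack[z].sum() for z in range(7)]
        top2 = sorted(sorted(range(7), key=lambda z: -sums[z])[:2])
        expected = stack[top2].max(axis=0)
        assert np.array_equal(brightest_substack_projection(stack, k=2),
                              expected)

    def test_roi_restricts_ranking(self):
        stack = np.zeros((3, 4, 4))
        stack[0, 0, 0] = 100.0  # bright outside ROI
        stack[2, 2:, 2:] = 5.0
        roi = np.zeros((4, 4), bool)
        roi[2:, 2:] = True
        out = brightest_substack_projection(stack, k=1, roi_mask=roi)
        assert np.array_equal(out, stack[2])

    def test_invalid_k(self):
        stack = np.zeros((2, 4, 4))
        with pytest.raises(ValueError):
            brightest_substack_projection(stack, k=3)
        with pytest.raises(ValueError):
            brightest_substack_projection(stack, k=0)


class TestRollingBall:
    def test_constant_image_zeroed(self):
        out = rolling_ball_subtract(np.full((64, 64), 120.0), radius=50)
        assert np.allclose(out, 0.0)
        assert np.all(out >= 0)

    def test_small_peak_preserved(self):
        img = np.zeros((128, 128))
        img[60:63, 60:63] = 200.0
        out = rolling_ball_subtract(img, radius=50)
        assert abs(out[61, 61] - 200.0) <= 1.0

    def test_wide_dome_mostly_removed(self):
        yy, xx = np.mgrid[:128, :128]
        r2 = (yy - 64) ** 2 + (xx - 64) ** 2
        dome_radius = 400.0
        height = 100.0
        dome = height * np.sqrt(np.clip(1 - r2 / dome_radius**2, 0, None))
        out = rolling_ball_subtract(dome, radius=50)
        assert out.max() <= 0.10 * height

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((8, 8)), radius=0)


class TestRoiMean:
    def test_constant_roi(self):
        img = np.full((6, 6), 42.0)
        roi = np.zeros((6, 6), bool)
        roi[2:4, 2:4] = True
        assert roi_mean(img, roi) == 42.0

    def test_disjoint_rois_area_weighted(self, rng):
        img = rng.uniform(0, 10, (8, 8))
        r1 = np.zeros((8, 8), bool)
        r2 = np.zeros((8, 8), bool)
        r1[:2, :2] = True
        r2[5:, 5:] = True
        combined = roi_mean(img, r1 | r2)
        expected = (roi_mean(img, r1) * r1.sum() + roi_mean(img, r2) * r2.sum()) \
            / (r1.sum() + r2.sum())
        assert combined == pytest.approx(expected)

    def test_matches_per_pixel_oracle(self, rng):
        img = rng.uniform(0, 10, (8, 8))
        roi = rng.random((8, 8)) > 0.5
        expected = sum(img[y, x] for y, x in np.argwhere(roi)) / roi.sum()
        assert roi_mean(img, roi) == pytest.approx(expected)

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError):
            roi_mean(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestPairAsymmetry:
    def test_tie_flagged_ratio_one(self):
        pm = pair_asymmetry(2, 10.0, 1, 10.0)
        assert pm.tie
        assert pm.ratio == 1.0
        assert pm.high_id == 1  # deterministic: smaller id wins the tie

    def test_high_low_assignment(self):
        pm = pair_asymmetry(1, 200.0, 2, 100.0)
        assert (pm.high_id, pm.low_id) == (1, 2)
        assert pm.ratio == pytest.approx(2.0)

    def test_swap_preserves_ratio(self):
        a = pair_asymmetry(1, 150.0, 2, 100.0)
        b = pair_asymmetry(2, 100.0, 1, 150.0)
        assert a.ratio == b.ratio
        assert a.high_id == b.high_id == 1

    def test_nonpositive_intensity_errors(self):
        with pytest.raises(ValueError):
            pair_asymmetry(1, 0.0, 2, 10.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.1, 1e5), st.floats(0.1, 1e5))
    def test_ratio_at_least_one(self, x, y):
        pm = pair_asymmetry(1, x, 2, y)
        assert pm.ratio >= 1.0
        assert pm.high_intensity >= pm.low_intensity
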