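"""Segmentation operator contracts and oracle equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ionoquant import synthetic as syn
from ionoquant.segmentation import (SegmentationParams, binarize, edt_shrink,
                                    gaussian_smooth, label_3d_components,
                                    segment_cells, split_by_ztracking,
                                    white_tophat_3d)

from conftest import disjoint_ellipsoid_mask, random_blob_mask
from oracles import (edt_distances_bruteforce, gaussian_bruteforce,
                     partitions_equal, tophat_bruteforce)


class TestWhiteTophat:
    def test_constant_image_maps_to_zero(self):
        out = white_tophat_3d(np.full((8, 16, 16), 100.0), (5, 5, 3))
        assert np.allclose(out, 0.0)

    def test_isolated_peak_retained(self):
        img = np.zeros((7, 15, 15))
        img[3, 7, 7] = 1000.0
        out = white_tophat_3d(img, (5, 5, 3))
        assert out[3, 7, 7] == 1000.0
        assert np.count_nonzero(out) == 1

    def test_matches_bruteforce_on_ramp_with_blob(self, rng):
        zz, yy, xx = np.mgrid[:16, :32, :32]
        img = 2.0 * yy + 1.0 * xx + 0.5 * zz
        img[6:10, 12:19, 12:19] += 500.0
        out = white_tophat_3d(img, footprint_yxz=(7, 7, 3))
        oracle = tophat_bruteforce(img, (3, 7, 7))
        assert np.allclose(out, oracle, rtol=1e-5, atol=1e-8)

    def test_footprint_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            white_tophat_3d(np.zeros((4, 8, 8)), (51, 51, 3))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(arrays(np.float64, (6, 10, 10),
                  elements=st.floats(0, 1000, allow_nan=False)))
    def test_residual_bounded_between_zero_and_input(self, img):
        out = white_tophat_3d(img, (5, 5, 3))
        assert np.all(out >= -1e-9)
        assert np.all(out <= img + 1e-9)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        out = gaussian_smooth(np.full((6, 12, 12), 200.0))
        assert np.allclose(out, 200.0)

    def test_impulse_normalized(self):
        img = np.zeros((9, 17, 17))
        img[4, 8, 8] = 1.0
        out = gaussian_smooth(img, (1.0, 1.0, 0.5))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_dense_convolution(self, rng):
        img = rng.uniform(0, 1000, (16, 16, 16))
        out = gaussian_smooth(img, (1.0, 1.0, 0.5))
        oracle = gaussian_bruteforce(img, (0.5, 1.0, 1.0))
        assert np.allclose(out, oracle, rtol=1e-5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4, 4)), (-1.0, 1.0, 1.0))


class TestBinarize:
    def test_threshold_is_inclusive(self):
        img = np.array([[[400.0, 500.0, 600.0]]])
        assert binarize(img, 500).tolist() == [[[False, True, True]]]

    def test_all_zero_empty_mask(self):
        assert not binarize(np.zeros((4, 8, 8)), 500).any()

    def test_count_matches_elementwise_oracle(self, rng):
        img = rng.uniform(0, 1000, (8, 16, 16))
        assert binarize(img, 500).sum() == int((img >= 500).sum())


class TestEdtShrink:
    def test_empty_mask_stays_empty(self):
        assert not edt_shrink(np.zeros((4, 8, 8), bool)).any()

    def test_thin_sheet_vanishes(self):
        mask = np.zeros((5, 16, 16), bool)
        mask[2] = True  # 1-voxel-thick sheet: all distances are 1
        assert not edt_shrink(mask, 2.0).any()

    def test_ball_matches_bruteforce_distance(self):
        zz, yy, xx = np.ogrid[:16, :16, :16]
        mask = (zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2 <= 25
        out = edt_shrink(mask, 2.0)
        dist = edt_distances_bruteforce(mask)
        assert np.array_equal(out, dist >= 2.0)

    def test_anti_extensive_and_distance_contract(self, rng):
        for _ in range(5):
            mask = random_blob_mask(rng)
            out = edt_shrink(mask, 2.0)
            assert not (out & ~mask).any()  # output subset of input
            dist = edt_distances_bruteforce(mask)
            assert np.all(dist[out] >= 2.0)
            removed = mask & ~out
            assert np.all(dist[removed] < 2.0)


class TestSplitByZTracking:
    def _cylinders(self, fuse_last=0):
        mask = np.zeros((10, 32, 32), bool)
        yy, xx = np.ogrid[:32, :32]
        c1 = (yy - 10) ** 2 + (xx - 16) ** 2 <= 16
        c2 = (yy - 22) ** 2 + (xx - 16) ** 2 <= 16
        mask[:, c1] = True
        mask[:, c2] = True
        if fuse_last:
            bridge = (np.abs(yy - 16) <= 7) & (np.abs(xx - 16) <= 2)
            mask[-fuse_last:, bridge] = True
        return mask

    def test_disjoint_cylinders_match_3d_components(self):
        mask = self._cylinders()
        res = split_by_ztracking(mask, min_object_voxels=0)
        assert res.n_cells == 2
        assert not res.merge_events
        assert partitions_equal(res.labels, label_3d_components(mask))

    def test_fused_cylinders_split_at_merge(self):
        mask = self._cylinders(fuse_last=3)
        res = split_by_ztracking(mask, min_object_voxels=0)
        assert res.n_cells == 2
        assert len(res.merge_events) == 1
        event = res.merge_events[0]
        assert event.slice_index == 7  # first fused slice
        for t in res.trajectories:
            assert t.status == "terminated_at_merge"
            assert t.last_slice == event.slice_index - 1
        # fused voxels stay unlabeled
        assert not res.labels[7:].any()
        # but 3D components see one object
        assert label_3d_components(mask).max() == 1

    def test_single_sphere_single_label(self):
        zz, yy, xx = np.ogrid[:12, :24, :24]
        mask = ((zz - 6) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 20
        res = split_by_ztracking(mask)
        assert res.n_cells == 1
        assert partitions_equal(res.labels, label_3d_components(mask))

    def test_merge_free_masks_equal_3d_components(self, rng):
        for _ in range(30):
            mask = disjoint_ellipsoid_mask(rng)
            res = split_by_ztracking(mask, min_object_voxels=0)
            assert partitions_equal(res.labels, label_3d_components(mask)), \
                "tracking and 3D components disagree on a merge-free mask"

    def test_no_label_spans_merge_event(self, rng):
        mask = self._cylinders(fuse_last=4)
        res = split_by_ztracking(mask, min_object_voxels=0)
        for event in res.merge_events:
            for t in res.trajectories:
                if t.label in event.trajectory_labels:
                    assert not (res.labels[event.slice_index:] == t.label).any()

    def test_trajectory_entries_contiguous_and_overlapping(self):
        mask = self._cylinders(fuse_last=3)
        res = split_by_ztracking(mask, min_object_voxels=0)
        for t in res.trajectories:
            slices = [e.slice_index for e in t.entries]
            assert slices == list(range(slices[0], slices[-1] + 1))
            for a, b in zip(slices, slices[1:]):
                overlap = (res.labels[a] == t.label) & (res.labels[b] == t.label)
                assert overlap.any()

    def test_min_object_voxels_filters_specks(self):
        mask = np.zeros((6, 16, 16), bool)
        mask[2, 4, 4] = True  # single-voxel speck
        mask[:, 10:14, 10:14] = True
        res = split_by_ztracking(mask, min_object_voxels=20)
        assert res.n_cells == 1
        res_all = split_by_ztracking(mask, min_object_voxels=0)
        assert res_all.n_cells == 2

    def test_traverse_from_last_slice(self):
        mask = self._cylinders(fuse_last=3)
        flipped = mask[::-1].copy()  # fused blob now at the first slices
        res = split_by_ztracking(flipped, traverse_from="last_slice",
                                 min_object_voxels=0)
        assert res.n_cells == 2
        assert len(res.merge_events) == 1


class TestSegmentCells:
    def test_all_zero_stack(self):
        res = segment_cells(np.zeros((8, 64, 64)))
        assert res.n_cells == 0
        assert not res.merge_events

    def test_single_cell_centroid(self, single_cell_spec):
        params = SegmentationParams(tophat_footprint_yxz=(31, 31, 3))
        stack, truth = syn.generate_stack(single_cell_spec, seed=0)
        res = segment_cells(stack, params)
        assert res.n_cells == 1
        pred = np.array(res.centroids()[1])
        true = np.array(truth.centroids[1])
        assert np.linalg.norm(pred - true) < 0.5

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_fused_cells_recovered(self, k):
        stack, truth = syn.generate_stack(syn.merge_scene_spec(k), seed=k)
        res = segment_cells(stack)
        assert res.n_cells == k
        assert len(res.merge_events) >= 1

    def test_params_recorded(self, single_cell_spec):
        params = SegmentationParams(threshold=600.0,
                                    tophat_footprint_yxz=(31, 31, 3))
        stack, _ = syn.generate_stack(single_cell_spec, seed=0)
        res = segment_cells(stack, params)
        assert res.params.threshold == 600.0

    def test_labels_disjoint_and_match_trajectories(self, fused_pair_spec):
        stack, _ = syn.generate_stack(fused_pair_spec, seed=2)
        res = segment_cells(stack)
        for t in res.trajectories:
            assert (res.labels == t.label).sum() == t.total_voxels


class TestParamsValidation:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold=-1)
        with pytest.raises(ValueError):
            SegmentationParams(edt_min=0)
        with pytest.raises(ValueError):
            SegmentationParams(connectivity_2d=6)

    def test_roundtrip_dict(self):
        p = SegmentationParams(threshold=700.0)
        assert SegmentationParams.from_dict(p.to_dict()) == p
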