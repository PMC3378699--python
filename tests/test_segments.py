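"""AHA partitioning, compartment splitting, regional courses, peaks."""

import numpy as np
import pandas as pd
import pytest

from mtpm.segments import (SegmentModel, angular_partition, bullseye,
                           default_windows, partition, peak_velocities,
                           regional_time_courses, split_epi_endo)


class TestSegmentModel:
    def test_slice_segment_counts(self):
        assert SegmentModel("basal").n_segments == 6
        assert SegmentModel("mid").n_segments == 6
        assert SegmentModel("apical").n_segments == 4

    def test_aha_ids_per_level(self):
        assert SegmentModel("basal").segment_ids == (1, 2, 3, 4, 5, 6)
        assert SegmentModel("mid").segment_ids == (7, 8, 9, 10, 11, 12)
        assert SegmentModel("apical").segment_ids == (13, 14, 15, 16)

    def test_anterior_centred_at_top_by_default(self):
        m = SegmentModel("basal")
        assert m.start_angle_deg == pytest.approx(90.0 - 30.0)


class TestPartition:
    def test_apical_has_four_quadrants(self, annulus_mask):
        mask, center, voxel = annulus_mask
        labels = partition(mask, center, SegmentModel("apical"), voxel)
        ids = np.unique(labels[labels > 0])
        np.testing.assert_array_equal(ids, [13, 14, 15, 16])
        counts = np.array([(labels == i).sum() for i in ids])
        # equiangular quadrants of a symmetric annulus
        assert np.ptp(counts) <= 0.02 * counts.mean() + 4

    def test_six_segments_balanced(self, annulus_mask):
        mask, center, voxel = annulus_mask
        labels = partition(mask, center, SegmentModel("basal"), voxel)
        counts = np.array([(labels == i).sum() for i in range(1, 7)])
        assert counts.sum() == mask.sum()
        assert np.ptp(counts) <= 0.02 * counts.mean() + 4

    def test_rotating_reference_permutes_labels(self, annulus_mask):
        mask, center, voxel = annulus_mask
        base = partition(mask, center, SegmentModel("basal"), voxel)
        rot = partition(mask, center,
                        SegmentModel("basal", reference_angle_deg=60.0 + 60.0),
                        voxel)
        expected = np.where(base > 0, (base - 1 - 1) % 6 + 1, 0)
        np.testing.assert_array_equal(rot, expected)

    def test_disjoint_cover(self, annulus_mask):
        mask, center, voxel = annulus_mask
        labels = partition(mask, center, SegmentModel("mid"), voxel)
        assert np.array_equal(labels > 0, mask)

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            angular_partition(np.zeros((4, 4), dtype=bool), (1, 1), 6, 0.0)


class TestSplitEpiEndo:
    def _labels_from_radii(self, radii):
        """One-row 'image' whose voxels sit at integer x with the given
        radii from a centre at x=0."""
        n = len(radii)
        labels = np.zeros((1, n), dtype=int)
        labels[0, :] = 1
        return labels, radii

    def test_median_split_four_voxels(self):
        labels = np.ones((1, 4), dtype=int)
        comp = split_epi_endo(labels, center_mm=(0.0, 0.0), voxel_mm=1.0)
        # radii 0,1,2,3 -> median 1.5 -> endo {0,1}, epi {2,3}
        np.testing.assert_array_equal(comp[0], [1, 1, 2, 2])

    def test_equal_radii_all_epi(self):
        labels = np.zeros((3, 3), dtype=int)
        labels[0, 1] = labels[1, 0] = labels[2, 1] = labels[1, 2] = 1
        comp = split_epi_endo(labels, center_mm=(1.0, 1.0), voxel_mm=1.0)
        assert np.all(comp[labels == 1] == 2)

    def test_matches_sort_and_halve(self, annulus_mask):
        mask, center, voxel = annulus_mask
        labels = partition(mask, center, SegmentModel("basal"), voxel)
        comp = split_epi_endo(labels, center, voxel)
        n = mask.shape[0]
        X, Y = np.meshgrid(np.arange(n) * voxel, np.arange(n) * voxel)
        r = np.hypot(X - center[0], Y - center[1])
        for sid in range(1, 7):
            sel = labels == sid
            med = np.median(np.sort(r[sel]))
            np.testing.assert_array_equal(comp[sel] == 1, r[sel] < med)
            # balanced halves up to the odd-count voxel
            n_endo = (comp[sel] == 1).sum()
            n_epi = (comp[sel] == 2).sum()
            assert abs(n_epi - n_endo) <= 1 + (r[sel] == med).sum()

    def test_tiny_segment_is_error(self):
        labels = np.zeros((2, 2), dtype=int)
        labels[0, 0] = 1
        with pytest.raises(ValueError, match="fewer than 2"):
            split_epi_endo(labels, (0.5, 0.5), 1.0)


def _uniform_courses(annulus, value=0.5, n_frames=4):
    mask, center, voxel = annulus
    model = SegmentModel("mid")
    shape = (n_frames,) + mask.shape
    v = np.where(mask, value, np.nan)[None].repeat(n_frames, axis=0)
    labels = np.stack([partition(mask, center, model, voxel)] * n_frames)
    comps = np.stack([split_epi_endo(labels[0], center, voxel)] * n_frames)
    centers = np.stack([np.asarray(center)] * n_frames)
    return model, v, labels, comps, centers, voxel


class TestRegionalTimeCourses:
    def test_uniform_field_equals_global_mean(self, annulus_mask):
        model, v, labels, comps, centers, voxel = \
            _uniform_courses(annulus_mask)
        rc = regional_time_courses(v, v, v, labels, comps, centers, model,
                                   voxel, 4.6)
        for key, series in rc.velocity.items():
            np.testing.assert_allclose(series, 0.5)

    def test_locality_of_segment_means(self, annulus_mask):
        model, v, labels, comps, centers, voxel = \
            _uniform_courses(annulus_mask)
        v2 = v.copy()
        v2[:, labels[0] == 7] *= 2.0
        rc = regional_time_courses(v2, v2, None, labels, comps, centers,
                                   model, voxel, 4.6)
        np.testing.assert_allclose(rc.velocity[(7, "full", "radial")], 1.0)
        np.testing.assert_allclose(rc.velocity[(8, "full", "radial")], 0.5)

    def test_count_weighted_means_reproduce_global(self, annulus_mask):
        mask, center, voxel = annulus_mask
        model = SegmentModel("mid")
        rng = np.random.default_rng(0)
        v = np.where(mask, rng.normal(size=mask.shape), np.nan)[None]
        labels = partition(mask, center, model, voxel)[None]
        comps = split_epi_endo(labels[0], center, voxel)[None]
        rc = regional_time_courses(v, v, None, labels, comps,
                                   np.asarray(center)[None], model, voxel,
                                   1.0)
        weighted = sum(rc.velocity[(sid, "full", "radial")][0]
                       * (labels[0] == sid).sum()
                       for sid in model.segment_ids)
        assert weighted / mask.sum() \
            == pytest.approx(np.nanmean(v[0]), abs=1e-9)

    def test_empty_region_reported_missing(self, annulus_mask):
        mask, center, voxel = annulus_mask
        model = SegmentModel("mid")
        half = mask.copy()
        # wipe the half-plane above the centre: top segments vanish
        half[: mask.shape[0] // 2] = False
        v = np.where(half, 1.0, np.nan)[None]
        labels = partition(half, center, model, voxel)[None]
        comps = split_epi_endo(labels[0], center, voxel)[None]
        rc = regional_time_courses(v, v, None, labels, comps,
                                   np.asarray(center)[None], model, voxel,
                                   1.0)
        missing = [sid for sid in model.segment_ids
                   if np.isnan(rc.velocity[(sid, "full", "radial")][0])]
        assert missing   # some segments truly empty, flagged NaN not zero


class TestPeakVelocities:
    def test_windows_and_peaks(self):
        series = np.array([0.1, 0.82, 0.3, -0.2, -1.5, -0.4])
        sw, dw = default_windows(6, es_frame=2)
        ps, pd_ = peak_velocities(series, sw, dw)
        assert ps == pytest.approx(0.82)
        assert pd_ == pytest.approx(-1.5)

    def test_constant_series(self):
        sw, dw = default_windows(6, 3)
        assert peak_velocities(np.full(6, 0.4), sw, dw) == (0.4, 0.4)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=20)
        sw, dw = default_windows(20, 8)
        ps, pd_ = peak_velocities(series, sw, dw)
        assert ps == max(series[i] for i in range(0, 9))
        assert pd_ == min(series[i] for i in range(9, 20))

    def test_missing_frames_propagate(self):
        series = np.array([0.1, np.nan, 0.3, 0.2])
        sw, dw = default_windows(4, 2)
        ps, _ = peak_velocities(series, sw, dw)
        assert np.isnan(ps)

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError):
            peak_velocities(np.zeros(4), [], [1])


class TestBullseye:
    def test_single_subject_zero_sd(self):
        table = bullseye([{i: 0.5 for i in range(1, 17)}])
        assert len(table) == 16
        np.testing.assert_allclose(table["sd"], 0.0)
        assert 17 not in set(table["segment"])

    def test_two_subject_closed_form_sd(self):
        v = 0.8
        table = bullseye([{1: v}, {1: -v}])
        assert table.loc[0, "mean"] == pytest.approx(0.0)
        assert table.loc[0, "sd"] == pytest.approx(v * np.sqrt(2))

    def test_inconsistent_segments_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            bullseye([{1: 0.1}, {2: 0.1}])

    def test_segment_17_rejected(self):
        with pytest.raises(ValueError, match="17"):
            bullseye([{17: 0.1}])
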