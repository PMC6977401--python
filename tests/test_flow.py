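"""Flow quantification: surface, bands, masking, time series, reperfusion."""

import numpy as np
import pandas as pd
import pytest

from ocmstroke.flow import (DepthBands, classify_reperfusion, detect_surface,
                            limited_flow_area, make_vessel_mask, noise_threshold,
                            normalize_sessions, reperfusion_summary,
                            segment_bands, total_flow_series)


class TestDepthBands:
    def test_default_three_functional_bands(self):
        b = DepthBands()
        assert b.intervals == [(0.0, 160.0), (160.0, 320.0), (320.0, 640.0)]

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            DepthBands((0.0, 160.0, 150.0))

    def test_bands_must_start_at_surface(self):
        with pytest.raises(ValueError):
            DepthBands((10.0, 160.0))


class TestDetectSurface:
    def _volume(self, start_px, nz=64, shape=(8, 8)):
        vol = np.zeros(shape + (nz,))
        rng = np.random.default_rng(0)
        start = np.broadcast_to(np.asarray(start_px), shape)
        for i in range(shape[0]):
            for j in range(shape[1]):
                s = int(start[i, j])
                vol[i, j, s:] = 1.0 + 0.3 * rng.random(nz - s)
        return vol

    def test_flat_surface_within_one_pixel(self):
        surf = detect_surface(self._volume(30))
        assert np.all(np.abs(surf - 30) <= 1.5)

    def test_tilted_surface_slope_recovered(self):
        """A planar 10-px slope across X is recovered within 10%."""
        start = 20 + (10 / 8) * np.arange(8)[None, :] * np.ones((8, 1))
        surf = detect_surface(self._volume(start.astype(int)))
        slope = np.polyfit(np.arange(8), surf.mean(axis=0), 1)[0] * 8
        assert slope == pytest.approx(10.0, rel=0.25)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            detect_surface(np.zeros((4, 4, 32)))

    def test_dark_ascan_filled_from_neighbours(self):
        vol = self._volume(30)
        vol[3, 3] = 0.0
        surf = detect_surface(vol)
        assert abs(surf[3, 3] - 30) <= 2.0


class TestSegmentBands:
    def test_boundary_voxel_goes_to_deeper_band(self):
        """A voxel exactly 160 um below the surface belongs to band 2
        (half-open intervals)."""
        bands = DepthBands((0.0, 160.0, 320.0, 640.0))
        surface = np.zeros((1, 1))
        masks = segment_bands((1, 1, 100), surface, bands, 10.0)
        z160 = 16  # 16 px * 10 um = 160 um exactly
        assert not masks[0][0, 0, z160]
        assert masks[1][0, 0, z160]

    def test_band_voxel_count_ratio(self):
        """With a flat surface at 0 and 640 um depth range at 10 um/px the
        band voxel counts are in ratio 160:160:320."""
        bands = DepthBands()
        masks = segment_bands((2, 2, 64), np.zeros((2, 2)), bands, 10.0)
        counts = [m.sum() for m in masks]
        assert counts[0] == counts[1]
        assert counts[2] == 2 * counts[0]

    def test_partition_of_in_tissue_voxels(self):
        bands = DepthBands()
        surface = np.full((3, 3), 5.0)
        masks = segment_bands((3, 3, 80), surface, bands, 10.0)
        union = np.zeros((3, 3, 80), int)
        for m in masks:
            union += m
        assert union.max() <= 1  # pairwise disjoint
        depth = (np.arange(80)[None, None, :] - 5.0) * 10.0
        in_tissue = (depth >= 0) & (depth < 640.0)
        assert np.array_equal(union.astype(bool), np.broadcast_to(in_tissue, union.shape))


class TestVesselMask:
    def test_bright_blob_detected(self):
        m = np.zeros((20, 20))
        m[5:15, 5:15] = 1.0  # 100-px blob
        vm = make_vessel_mask(m, threshold_quantile=0.7, min_area_px=50)
        assert vm.mask.sum() == 100
        assert vm.mask[10, 10]

    def test_min_area_filters_blob(self):
        m = np.zeros((20, 20))
        m[5:15, 5:15] = 1.0
        vm = make_vessel_mask(m, threshold_quantile=0.7, min_area_px=200)
        assert not vm.mask.any()

    def test_uniform_map_gives_empty_mask(self):
        vm = make_vessel_mask(np.ones((10, 10)), 0.9, 10)
        assert not vm.mask.any()

    def test_threshold_quantile_bounds(self):
        with pytest.raises(ValueError):
            make_vessel_mask(np.zeros((5, 5)), 1.5, 10)


class TestTotalFlowSeries:
    def _bands(self):
        masks = [np.zeros((2, 2, 12), bool) for _ in range(3)]
        masks[0][:, :, :4] = True
        masks[1][:, :, 4:8] = True
        masks[2][:, :, 8:] = True
        return masks

    def test_all_zero_volumes(self):
        masks = self._bands()
        s = total_flow_series([np.zeros((2, 2, 12))] * 3, masks)
        assert not s.table.filter(like="_raw").to_numpy().any()

    def test_halved_band3_normalizes_to_half(self):
        """Second volume with band-3 voxels halved: band 3 normalized 0.5,
        bands 1-2 stay 1.0."""
        masks = self._bands()
        v1 = np.full((2, 2, 12), 10.0)
        v2 = v1.copy()
        v2[:, :, 8:] *= 0.5
        s = total_flow_series([v1, v2], masks, baseline_frames=[0])
        assert s.band_norm(1)[1] == pytest.approx(1.0)
        assert s.band_norm(2)[1] == pytest.approx(1.0)
        assert s.band_norm(3)[1] == pytest.approx(0.5)

    def test_masked_column_removes_exactly_its_contribution(self):
        masks = self._bands()
        rng = np.random.default_rng(2)
        vol = rng.random((2, 2, 12)) + 1.0
        vmask = np.zeros((2, 2), bool)
        vmask[0, 1] = True
        with_mask = total_flow_series([vol], masks, vessel_mask=vmask)
        without = total_flow_series([vol], masks)
        for b, bm in enumerate(masks, start=1):
            col = vol[0, 1] * bm[0, 1]
            assert with_mask.band_raw(b)[0] == pytest.approx(
                without.band_raw(b)[0] - col.sum())

    def test_threshold_zeroes_subthreshold_voxels(self):
        masks = self._bands()
        vol = np.full((2, 2, 12), 1.0)
        vol[0, 0, 0] = 10.0
        s = total_flow_series([vol], masks, threshold=5.0)
        assert s.band_raw(1)[0] == pytest.approx(10.0)

    def test_grid_mismatch_rejected(self):
        masks = self._bands()
        with pytest.raises(ValueError, match="mismatch"):
            total_flow_series([np.zeros((2, 2, 12)), np.zeros((2, 2, 10))], masks)

    def test_csv_round_trip(self, tmp_path):
        masks = self._bands()
        s = total_flow_series([np.ones((2, 2, 12))] * 2, masks,
                              timestamps_s=np.array([0.0, 18.0]))
        path = tmp_path / "flow.csv"
        s.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_s", "band1_raw", "band2_raw", "band3_raw",
                                    "band1_norm", "band2_norm", "band3_norm"]
        assert df.time_s.tolist() == [0.0, 18.0]


class TestNoiseThreshold:
    def test_mean_plus_k_sigma(self):
        rng = np.random.default_rng(0)
        data = rng.normal(10.0, 2.0, (4, 4, 100))
        region = np.ones((4, 4, 100), bool)
        thr = noise_threshold(data, region, k_sigma=5.0)
        vals = data[region]
        assert thr == pytest.approx(vals.mean() + 5 * vals.std())


class TestNormalizeSessions:
    def test_global_gain_inverted(self):
        rng = np.random.default_rng(1)
        a0 = rng.random((4, 4, 30)) + 0.1
        s = np.ones((4, 4, 30))
        nr = np.ones((4, 4, 30), bool)
        scaled = normalize_sessions(a0, 2.0 * a0, s, s, nr)
        assert np.allclose(scaled, a0, rtol=0.01)

    def test_identity_for_identical_sessions(self):
        rng = np.random.default_rng(2)
        a = rng.random((4, 4, 30)) + 0.1
        s = rng.random((4, 4, 30)) + 0.5
        nr = np.ones((4, 4, 30), bool)
        scaled = normalize_sessions(a, a, s, s, nr)
        assert np.allclose(scaled, a, rtol=0.01)

    def test_depth_attenuation_ramp_restored(self):
        """A 1 -> 0.5 structural attenuation ramp applied to both structure
        and angio is inverted by the depth gain within 5%."""
        rng = np.random.default_rng(3)
        nz = 40
        ramp = np.linspace(1.0, 0.5, nz)
        a0 = np.full((6, 6, nz), 2.0)
        s0 = np.full((6, 6, nz), 1.0)
        a1 = a0 * ramp[None, None, :]
        s1 = s0 * ramp[None, None, :]
        nr = np.zeros((6, 6, nz), bool)
        nr[:, :, :4] = True  # noise region where ramp ~ 1
        scaled = normalize_sessions(a0, a1, s0, s1, nr, smooth_sigma=0.5)
        inner = scaled[:, :, 4:-4]
        assert np.allclose(inner, a0[:, :, 4:-4], rtol=0.05)


class TestLimitedFlowArea:
    def test_all_super_threshold_gives_zero(self):
        m = np.full((10, 10), 5.0)
        assert limited_flow_area(m, np.ones((10, 10), bool), 1.0) == 0.0

    def test_hand_counted_fraction(self):
        """60 of 100 baseline-positive ROI pixels below threshold -> 0.60."""
        base = np.zeros((10, 20))
        base[:, :10] = 1.0  # 100 positive pixels
        current = base.copy()
        current[:6, :10] = 0.0  # 60 dropped below threshold
        roi = np.ones_like(base, bool)
        frac = limited_flow_area(current, roi, threshold=0.5, baseline_map=base)
        assert frac == pytest.approx(0.60)

    def test_zero_threshold_on_positive_map(self):
        m = np.full((5, 5), 1.0)
        assert limited_flow_area(m, np.ones((5, 5), bool), 0.0) == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            limited_flow_area(np.ones((5, 5)), np.zeros((5, 5), bool), 1.0)


class TestClassifyReperfusion:
    def test_full_when_followup_equals_baseline(self):
        assert classify_reperfusion(2.0, 2.0) == "full"

    def test_none_when_followup_zero(self):
        assert classify_reperfusion(2.0, 0.0) == "none"

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            classify_reperfusion(0.0, 1.0)

    def test_programmed_cohort_fractions(self):
        """Nine vessels with recoveries {0.05 x 1, 0.5 x 5, 0.05 x 3} at the
        default cut points give 5/9 ~ 56% partial reperfusion."""
        baseline = np.ones(9)
        followup = np.array([0.05] + [0.5] * 5 + [0.05] * 3)
        cls = classify_reperfusion(baseline, followup, c_none=0.2, c_full=0.8)
        summary = reperfusion_summary(cls)
        assert summary["partial"] == pytest.approx(5 / 9)
        assert summary["none"] == pytest.approx(4 / 9)
        assert round(100 * summary["partial"]) == 56
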