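"""Reconstruction: k-linearization, dispersion, FFT, cropping, structure."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocmstroke.forward import simulate_spectra
from ocmstroke.protocol import AcquisitionProtocol
from ocmstroke.recon import (CalibrationProfile, ComplexVolume, axial_peak,
                             compensate_dispersion, crop_z, linearize_k,
                             reconstruct_series, structural_volume)
from ocmstroke.scene import build_scene

from conftest import make_single_scatterer_series


class TestLinearizeK:
    def test_identity_map_is_exact(self):
        rng = np.random.default_rng(0)
        spec = rng.normal(size=128)
        cal = CalibrationProfile.identity(128)
        assert np.array_equal(linearize_k(spec, cal), spec)

    def test_constant_spectrum_preserved(self):
        cal = CalibrationProfile(np.linspace(0, 127, 128) ** 1.02 / 127 ** 0.02,
                                 np.zeros(0))
        out = linearize_k(np.full(128, 3.5), cal)
        assert np.allclose(out, 3.5, atol=1e-9)

    def test_warped_fringe_relinearizes_to_true_depth(self):
        """A fringe recorded on a quadratically warped grid lands within one
        depth pixel of the scatterer's true position after linearization."""
        series, p = make_single_scatterer_series(500.0, warp=0.15)
        cal = CalibrationProfile.from_series(series)
        vol = reconstruct_series(series, cal, (6, 256), dc_subtract=False)
        peak = np.abs(vol.data[0, 0, 0]).argmax() + 6
        assert abs(peak - 500.0 / p.dz_air_um) <= 1.0

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            CalibrationProfile(np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            linearize_k(np.zeros(64), CalibrationProfile.identity(128))


class TestDispersion:
    def test_zero_coefficients_are_identity(self):
        spec = np.random.default_rng(1).normal(size=64)
        out = compensate_dispersion(spec, np.zeros(0))
        assert np.allclose(out, spec)

    def test_truth_compensation_restores_fwhm(self):
        """50 rad of quadratic phase at the band edge: compensating with the
        synthesis coefficients restores the axial FWHM to within 10% of the
        dispersion-free width."""
        free, _ = make_single_scatterer_series(900.0)
        cal0 = CalibrationProfile.from_series(free)
        _, fw_free = axial_peak(
            reconstruct_series(free, cal0, (6, 256), dc_subtract=False).data[0, 0, 0])

        disp, _ = make_single_scatterer_series(900.0, dispersion=[50.0])
        cal = CalibrationProfile.from_series(disp)  # carries truth coefficients
        _, fw_comp = axial_peak(
            reconstruct_series(disp, cal, (6, 256), dc_subtract=False).data[0, 0, 0])
        assert fw_comp / fw_free <= 1.1

        # uncompensated control: clearly broadened
        cal_none = CalibrationProfile(cal.k_resample_map, np.zeros(0))
        _, fw_un = axial_peak(
            reconstruct_series(disp, cal_none, (6, 256), dc_subtract=False).data[0, 0, 0])
        assert fw_un > 2 * fw_free

    def test_double_compensation_rebroadens(self):
        disp, _ = make_single_scatterer_series(900.0, dispersion=[50.0])
        cal = CalibrationProfile.from_series(disp)
        _, fw_once = axial_peak(
            reconstruct_series(disp, cal, (6, 256), dc_subtract=False).data[0, 0, 0])
        cal2 = CalibrationProfile(cal.k_resample_map, np.array([100.0]))
        _, fw_twice = axial_peak(
            reconstruct_series(disp, cal2, (6, 256), dc_subtract=False).data[0, 0, 0])
        assert fw_twice > fw_once


class TestReconstructSeries:
    def test_all_zero_series_reconstructs_to_zero(self):
        p = AcquisitionProtocol(n_y=2, n_x=3, n_repeats=2, n_spectral=64,
                                x_range_mm=0.05, y_range_mm=0.05)
        scene = build_scene((2, 3, 8), (17.2, 17.2, 2.5), [], 0,
                            surface_depth_um=0.0, tissue_reflectivity=0.0)
        series = simulate_spectra(scene, p, seed=0)
        series = dataclasses.replace(series, data=np.zeros_like(series.data))
        vol = reconstruct_series(series, CalibrationProfile.identity(64), (4, 20),
                                 dc_subtract=False)
        assert not np.abs(vol.data).any()

    def test_crop_index_arithmetic(self):
        """A scatterer at depth pixel 100, cropped to [50, 300), appears at
        cropped index 50."""
        series, p = make_single_scatterer_series(100 * 2120.0 / 256)
        cal = CalibrationProfile.from_series(series)
        vol = reconstruct_series(series, cal, (50, 250), window=None,
                                 dc_subtract=False)
        assert np.abs(vol.data[0, 0, 0]).argmax() == 50

    def test_out_of_range_crop_rejected(self):
        series, _ = make_single_scatterer_series(300.0)
        cal = CalibrationProfile.from_series(series)
        with pytest.raises(ValueError, match="crop"):
            reconstruct_series(series, cal, (0, 400))

    def test_parseval_energy_conservation(self):
        """Windowless FFT stage preserves total signal energy."""
        series, _ = make_single_scatterer_series(400.0)
        cal = CalibrationProfile.from_series(series)
        vol = reconstruct_series(series, cal, window=None, dc_subtract=False,
                                 keep="full", out_dtype=np.complex128)
        e_in = float((series.data.astype(float) ** 2).sum())
        e_out = float((np.abs(vol.data) ** 2).sum())
        assert e_out == pytest.approx(e_in, rel=1e-9)

    def test_tilt_correction_flattens_interface(self):
        """A 10-px planar tilt across X is reduced to <=1 px residual slope."""
        p = AcquisitionProtocol(n_y=4, n_x=32, n_repeats=1, n_spectral=512,
                                x_range_mm=0.55, y_range_mm=0.069)
        scene = build_scene((4, 32, 256), (17.2, 17.2, 2.5), [], 1,
                            surface_depth_um=30.0,
                            surface_tilt_um_per_px=(0.0, 10 * 6.13 / 32))
        series = simulate_spectra(scene, p, seed=4)
        cal = CalibrationProfile.from_series(series)
        vol = reconstruct_series(series, cal, (4, 132), tilt_correct=True)
        from ocmstroke.recon import detect_interface
        iface = detect_interface(vol)
        slope = np.polyfit(np.arange(32), iface.mean(axis=0), 1)[0] * 32
        assert abs(slope) <= 1.0


class TestCropping:
    def _volume(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(2, 2, 3, 40)) + 1j * rng.normal(size=(2, 2, 3, 40))
        return ComplexVolume(data=data, dz_air_um=2.07, dx_um=3.7, dy_um=3.7,
                             z_crop=(0, 40))

    def test_crop_idempotent(self):
        vol = self._volume()
        once = crop_z(vol, (5, 30))
        twice = crop_z(once, (0, 25))
        assert np.array_equal(once.data, twice.data)
        assert twice.z_crop == (5, 30)

    @given(a1=st.integers(0, 30), l1=st.integers(5, 10),
           a2=st.integers(0, 8), l2=st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_nested_crops_compose_to_intersection(self, a1, l1, a2, l2):
        from hypothesis import assume
        assume(a2 < l1)  # the inner interval must intersect the first crop
        vol = self._volume()
        inner = crop_z(crop_z(vol, (a1, a1 + l1)), (a2, a2 + l2))
        direct = crop_z(vol, (a1 + a2, min(a1 + a2 + l2, a1 + l1)))
        assert inner.z_crop == direct.z_crop
        assert np.array_equal(inner.data, direct.data)


class TestStructuralVolume:
    def test_identical_repeats_keep_single_magnitude(self):
        data = np.full((1, 6, 1, 1), 3 + 4j, np.complex64)
        vol = ComplexVolume(data, 2.07, 3.7, 3.7, (0, 1))
        assert structural_volume(vol).data[0, 0, 0] == pytest.approx(5.0)

    def test_alternating_phasors_cancel_coherently(self):
        seq = np.array([1, -1, 1, -1, 1, -1], np.complex64).reshape(1, 6, 1, 1)
        vol = ComplexVolume(seq, 2.07, 3.7, 3.7, (0, 1))
        assert structural_volume(vol).data[0, 0, 0] == pytest.approx(0.0)
        assert structural_volume(vol, "incoherent").data[0, 0, 0] == pytest.approx(1.0)

    def test_all_zero_volume(self):
        vol = ComplexVolume(np.zeros((2, 3, 2, 4), np.complex64), 2.07, 3.7, 3.7, (0, 4))
        assert not structural_volume(vol).data.any()

    def test_coherent_averaging_suppresses_noise_variance(self):
        """Averaging 6 repeats reduces additive-noise variance by ~6x
        (within +-20%) on a static phantom."""
        p = AcquisitionProtocol(n_y=8, n_x=16, n_repeats=6, n_spectral=512,
                                x_range_mm=0.275, y_range_mm=0.138)
        scene = build_scene((8, 16, 128), (17.2, 17.2, 2.5), [], 2)
        # tissue pushed deep (400 um air gap) so shallow bins are pure noise
        series = simulate_spectra(scene, p, seed=5, noise_std=0.02,
                                  z_offset_air_um=400.0)
        cal = CalibrationProfile.from_series(series)
        vol = reconstruct_series(series, cal, (4, 132))
        single = np.abs(vol.data[:, 0, :, 2:30])
        averaged = structural_volume(vol).data[:, :, 2:30]
        ratio = averaged.var() / single.var()
        assert ratio == pytest.approx(1 / 6, rel=0.2)
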