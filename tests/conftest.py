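"""Shared fixtures: tiny phantoms, single-scatterer acquisitions, protocols."""

from __future__ import annotations

import numpy as np
import pytest

from ocmstroke.forward import OCMSimulator, ScattererSet, warped_k_grid
from ocmstroke.protocol import AcquisitionProtocol
from ocmstroke.scene import Vessel, build_scene


@pytest.fixture
def small_protocol() -> AcquisitionProtocol:
    """Desk-scale protocol: 64 x 64 lateral grid, 512 spectral pixels."""
    return AcquisitionProtocol(n_y=64, n_x=64, n_spectral=512,
                               x_range_mm=64 * 17.2e-3, y_range_mm=64 * 17.2e-3)


def make_single_scatterer_series(
    z_opt_um: float,
    n_spectral: int = 512,
    warp: float = 0.0,
    dispersion=None,
    amp: float = 5.0,
    seed: int = 0,
):
    """One A-scan containing a single scatterer at a known optical depth
    (air-equivalent; refractive index 1, no offset)."""
    protocol = AcquisitionProtocol(n_y=1, n_x=1, n_repeats=1, n_spectral=n_spectral,
                                   x_range_mm=0.0172, y_range_mm=0.0172)
    scene = build_scene((1, 1, 8), (17.2, 17.2, 2.5), [], seed,
                        surface_depth_um=0.0, tissue_reflectivity=0.0,
                        refractive_index=1.0)
    scatterers = ScattererSet(
        z_um=np.array([z_opt_um]), amp=np.array([amp]), phase0=np.array([0.0]),
        col=np.array([0]), vessel_index=np.array([-1]), step_um=np.array([0.0]),
        n_cols=1)
    k = warped_k_grid(n_spectral, protocol.z_range_air_mm * 1e3, warp) if warp else None
    sim = OCMSimulator(scene, protocol, seed=seed, scatterers=scatterers,
                       k_grid=k, z_offset_air_um=0.0, refractive_index=1.0,
                       dispersion_coeffs=dispersion)
    return sim.frame(0), protocol


@pytest.fixture
def single_vessel_scene():
    """32 x 64 scene with one flowing pial vessel along y (a few x columns in
    every B-scan) over static tissue."""
    vessels = [Vessel(1, "y", radius_um=10.0, depth_um=150.0,
                      flow_class="pial", x_um=20 * 17.2, band=1)]
    return build_scene((32, 64, 256), (17.2, 17.2, 2.5), vessels, 3)


@pytest.fixture
def static_scene():
    """Vessel-free static tissue scene."""
    return build_scene((8, 16, 256), (17.2, 17.2, 2.5), [], 2)


def protocol_for_scene(scene) -> AcquisitionProtocol:
    ny, nx, _ = scene.shape
    dy, dx, _ = scene.pitch_um
    return AcquisitionProtocol(n_y=ny, n_x=nx, n_spectral=512,
                               x_range_mm=nx * dx * 1e-3, y_range_mm=ny * dy * 1e-3)


def reconstruct_scene(scene, seed=7, noise_std=0.0, bulk_phases=None,
                      dc_subtract=True, **sim_kw):
    """Simulate one frame of a scene and reconstruct it at high precision."""
    from ocmstroke.recon import CalibrationProfile, reconstruct_series

    protocol = protocol_for_scene(scene)
    sim = OCMSimulator(scene, protocol, seed=seed, noise_std=noise_std,
                       bulk_phases=bulk_phases, **sim_kw)
    frame = sim.frame(0)
    cal = CalibrationProfile.from_series(frame)
    vol = reconstruct_series(frame, cal, (4, 132), dc_subtract=dc_subtract,
                             out_dtype=np.complex128)
    return vol, sim


def vessel_free_column_mask(scene, vol):
    """(Y, X, Z) in-tissue mask restricted to vessel-free columns."""
    z = np.arange(vol.z_crop[0], vol.z_crop[1]) * vol.dz_air_um
    surf_opt = 100.0 + scene.refractive_index * scene.surface_depth_um
    deep = 100.0 + scene.refractive_index * scene.z_extent_um
    in_tissue = (z[None, None, :] >= surf_opt[:, :, None] + 3 * vol.dz_air_um) & \
                (z[None, None, :] <= deep)
    return in_tissue & ~scene.vessel_columns()[:, :, None]
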