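"""Canned study runs: the synthetic stroke experiment end to end.

These helpers wire the canonical phantom through simulation, reconstruction,
angiography and quantification with the study's default conditions, and are
shared by the test suite, the acceptance script and the CLI examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angio import build_angio_volume
from .flow import (DepthBands, FlowTimeSeries, detect_surface, make_vessel_mask,
                   noise_threshold, segment_bands, total_flow_series)
from .forward import OCMSimulator
from .pipeline import truth_static_mask
from .protocol import AcquisitionProtocol
from .recon import CalibrationProfile, reconstruct_series, structural_volume
from .scene import Scene, StrokeTimecourse, default_stroke_scene, make_timecourse

#: desk-scale protocol matching the canonical 64 x 64 phantom
DEFAULT_Z_CROP = (4, 132)


def desk_protocol(shape=(64, 64, 256), pitch_um=(17.2, 17.2, 2.5),
                  n_spectral: int = 512, n_repeats: int = 6) -> AcquisitionProtocol:
    ny, nx, _ = shape
    dy, dx, _ = pitch_um
    return AcquisitionProtocol(
        n_y=ny, n_x=nx, n_repeats=n_repeats, n_spectral=n_spectral,
        x_range_mm=nx * dx * 1e-3, y_range_mm=ny * dy * 1e-3)


@dataclass
class StrokeStudyResult:
    scene: Scene
    timecourse: StrokeTimecourse
    series: FlowTimeSeries
    surface_px: np.ndarray
    angio_volumes: list[np.ndarray]
    structural_baseline: object
    threshold: float
    enface_baseline: np.ndarray
    enface_by_frame: list[np.ndarray]
    dz_tissue_um: float

    def plateau(self, band: int, stage: str, skip: int = 0) -> float:
        """Mean normalized band value over a stage's frames."""
        frames = self.timecourse.frames(stage)[skip:]
        return float(np.mean(self.series.band_norm(band)[frames]))


def run_stroke_study(
    seed: int,
    *,
    n_baseline: int = 4,
    n_occlusion: int = 6,
    n_recovery: int = 0,
    occlusion_factor_by_band=0.1,
    recovery_factor_by_band=1.0,
    spared_vessels: tuple[int, ...] = (),
    shape=(64, 64, 256),
    pitch_um=(17.2, 17.2, 2.5),
    n_spectral: int = 512,
    noise_std: float = 0.004,
    bulk_std_rad: float = 0.5,
    threshold_k_sigma: float = 5.0,
    z_crop: tuple[int, int] = DEFAULT_Z_CROP,
    bands: DepthBands | None = None,
    shadow_scramble_rad: float = 0.0,
) -> StrokeStudyResult:
    """Simulate and quantify one three-stage stroke time course."""
    scene = default_stroke_scene(seed, shape=shape, pitch_um=pitch_um)
    protocol = desk_protocol(shape, pitch_um, n_spectral)
    timecourse = make_timecourse(
        scene, n_baseline=n_baseline, n_occlusion=n_occlusion, n_recovery=n_recovery,
        occlusion_factor_by_band=occlusion_factor_by_band,
        recovery_factor_by_band=recovery_factor_by_band,
        spared_vessels=spared_vessels)
    sim = OCMSimulator(scene, protocol, seed=seed, timecourse=timecourse,
                       noise_std=noise_std, bulk_std_rad=bulk_std_rad,
                       shadow_scramble_rad=shadow_scramble_rad)

    calibration = None
    static_mask = None
    structural0 = None
    angio_volumes: list[np.ndarray] = []
    enface_frames: list[np.ndarray] = []
    timestamps = []
    for i in range(timecourse.n_frames):
        frame = sim.frame(i)
        if calibration is None:
            calibration = CalibrationProfile.from_series(frame)
        cvol = reconstruct_series(frame, calibration, z_crop)
        if structural0 is None:
            structural0 = structural_volume(cvol)
            static_mask = truth_static_mask(scene, sim, cvol.z_crop,
                                            cvol.dz_air_um, cvol.data.shape[-1])
            dz_tissue = cvol.dz_tissue_um
        av = build_angio_volume(cvol, static_mask, noise_region=static_mask)
        angio_volumes.append(av.data)
        enface_frames.append(av.data.mean(axis=-1))
        timestamps.append(float(frame.timestamps_s[0]))

    surface_px = detect_surface(structural0)
    if bands is None:
        bands = DepthBands()
    band_masks = segment_bands(structural0.data.shape, surface_px, bands, dz_tissue)

    baseline_frames = timecourse.frames("baseline")
    base_mean = np.mean([angio_volumes[i] for i in baseline_frames], axis=0)
    thr = noise_threshold(base_mean, static_mask, threshold_k_sigma)

    band1 = band_masks[0]
    ef1 = np.where(band1, base_mean, 0.0).sum(axis=-1) / np.maximum(band1.sum(axis=-1), 1)
    vmask = make_vessel_mask(ef1, 0.9, 40)

    series = total_flow_series(
        angio_volumes, band_masks, timestamps_s=np.asarray(timestamps),
        vessel_mask=vmask, threshold=thr, baseline_frames=baseline_frames)
    return StrokeStudyResult(
        scene=scene, timecourse=timecourse, series=series, surface_px=surface_px,
        angio_volumes=angio_volumes, structural_baseline=structural0,
        threshold=thr, enface_baseline=base_mean.mean(axis=-1),
        enface_by_frame=enface_frames, dz_tissue_um=dz_tissue)
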