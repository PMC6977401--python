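"""End-to-end orchestration: simulate -> reconstruct -> angio -> project ->
quantify, plus the serial-section infarct branch, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .angio import build_angio_volume
from .config import PipelineConfig
from .flow import (DepthBands, detect_surface, make_vessel_mask, noise_threshold,
                   segment_bands, total_flow_series)
from .forward import OCMSimulator
from .infarct import align_stack, infarct_metrics, segment_infarct
from .io import write_label_nifti, write_section_stack, write_volume_tiff
from .projection import depth_coded_angio, enface
from .protocol import AcquisitionProtocol, protocol_timing
from .recon import CalibrationProfile, reconstruct_series, structural_volume
from .scene import default_stroke_scene, make_timecourse
from .sections import SectionStackSpec, simulate_sections

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int | None
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: float = 0.0
    finished: float = 0.0
    log_path: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()


def protocol_from_config(config: PipelineConfig) -> AcquisitionProtocol:
    sim = config.simulate
    ny, nx, _ = sim.grid
    dy, dx, _ = sim.pitch_um
    return AcquisitionProtocol(
        n_y=ny, n_x=nx, n_repeats=sim.n_repeats, n_spectral=sim.n_spectral,
        x_range_mm=nx * dx * 1e-3, y_range_mm=ny * dy * 1e-3,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Raises RuntimeError naming the failing stage; a partial manifest is
    persisted on failure.  Deterministic stages produce identical output
    checksums under identical config + seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__,
                           seed=config.seed, started=time.time(),
                           log_path=str(out_dir / "run.log"))
    (out_dir / "config.json").write_text(config.model_dump_json(indent=2))

    def register(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out_dir))] = _sha256(path)

    try:
        angio_volumes = None
        structural0 = None
        scene = None
        timecourse = None
        timestamps = None
        angio_geo = None

        if config.stages.simulate and config.stages.reconstruct and config.stages.angio:
            scene, timecourse, angio_volumes, structural0, timestamps, angio_geo = \
                _run_imaging_stages(config)

        if config.stages.quantify:
            if angio_volumes is None:
                raise RuntimeError("stage 'quantify' missing dependency: angio volumes")
            _run_quantify(config, scene, timecourse, angio_volumes, structural0,
                          timestamps, angio_geo, out_dir, register)

        if config.stages.project:
            if angio_volumes is None:
                raise RuntimeError("stage 'project' missing dependency: angio volumes")
            _run_project(config, angio_volumes, structural0, angio_geo, out_dir, register)

        if config.stages.infarct:
            _run_infarct(config, out_dir, register)

    except RuntimeError:
        manifest.finished = time.time()
        manifest.to_json(out_dir / "manifest.json")
        raise
    manifest.finished = time.time()
    manifest.to_json(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _run_imaging_stages(config: PipelineConfig):
    sim_cfg = config.simulate
    protocol = protocol_from_config(config)
    scene = default_stroke_scene(config.seed, shape=sim_cfg.grid, pitch_um=sim_cfg.pitch_um)
    fr = sim_cfg.frames
    timecourse = make_timecourse(
        scene,
        n_baseline=fr.get("baseline", 4), n_dye=fr.get("dye", 0),
        n_occlusion=fr.get("occlusion", 0), n_recovery=fr.get("recovery", 0),
        occlusion_factor_by_band=sim_cfg.occlusion_factor,
        recovery_factor_by_band=sim_cfg.recovery_factor,
    )
    from .forward import warped_k_grid
    k_grid = None
    if sim_cfg.k_warp:
        k_grid = warped_k_grid(sim_cfg.n_spectral, protocol.z_range_air_mm * 1e3,
                               sim_cfg.k_warp)
    simulator = OCMSimulator(
        scene, protocol, seed=config.seed, timecourse=timecourse,
        dispersion_coeffs=np.asarray(sim_cfg.dispersion) if sim_cfg.dispersion else None,
        bulk_std_rad=sim_cfg.bulk_std_rad, noise_std=sim_cfg.noise_std,
        k_grid=k_grid, shadow_scramble_rad=sim_cfg.shadow_scramble_rad,
    )
    rc = config.recon
    angio_volumes = []
    structural0 = None
    timestamps = []
    calibration = None
    angio_geo = None
    static_mask = None
    for frame_idx in range(timecourse.n_frames):
        series = simulator.frame(frame_idx)
        if calibration is None:
            calibration = CalibrationProfile.from_series(series)
        cvol = reconstruct_series(
            series, calibration, rc.z_crop, window=rc.window,
            interpolation=rc.interpolation, dc_subtract=rc.dc_subtract,
            tilt_correct=rc.tilt_correct, refractive_index=rc.refractive_index)
        if structural0 is None:
            structural0 = structural_volume(cvol)
            angio_geo = {"dz_air_um": cvol.dz_air_um, "z_crop": cvol.z_crop,
                         "refractive_index": cvol.refractive_index}
            if config.angio.static_mask == "truth":
                static_mask = truth_static_mask(scene, simulator, cvol.z_crop,
                                                cvol.dz_air_um, cvol.data.shape[-1])
        av = build_angio_volume(
            cvol, static_mask if static_mask is not None else "auto",
            pairs=config.angio.pairs, averaging=config.angio.averaging)
        angio_volumes.append(av.data)
        timestamps.append(float(series.timestamps_s[0]))
    return scene, timecourse, angio_volumes, structural0, np.asarray(timestamps), angio_geo


def truth_static_mask(scene, simulator: OCMSimulator, z_crop, dz_air_um, nz) -> np.ndarray:
    """(Y, X, Z) static region from scene truth on the reconstructed grid.

    Keeps in-tissue voxels strictly above the shallowest vessel of each
    column (vessel voxels and their axial shadow are excluded; vessel-free
    columns contribute their full tissue depth)."""
    ny, nx, nz_scene = scene.shape
    dz_scene = scene.pitch_um[2]
    zc = (np.arange(nz_scene) + 0.5) * dz_scene
    has_vessel = scene.vessel_map > 0
    first = np.argmax(has_vessel, axis=2)
    top_um = np.where(has_vessel.any(axis=2), zc[first], np.inf)  # geometric um
    top_opt = np.where(np.isfinite(top_um), simulator.z_optical(top_um), np.inf)

    surf_opt = simulator.z_optical(scene.surface_depth_um)
    z_px = np.arange(z_crop[0], z_crop[0] + nz) * dz_air_um  # optical depth per bin
    in_tissue = z_px[None, None, :] >= (surf_opt[:, :, None] + 3 * dz_air_um)
    deep_ok = z_px[None, None, :] <= simulator.z_optical(scene.z_extent_um)
    above_vessels = z_px[None, None, :] < (top_opt[:, :, None] - 2 * dz_air_um)
    return in_tissue & deep_ok & above_vessels


def _quantify_geometry(config, scene, structural0, angio_geo):
    bands = DepthBands(config.quantify.band_edges_um)
    surface_px = detect_surface(structural0)
    dz_tissue = angio_geo["dz_air_um"] / angio_geo["refractive_index"]
    band_masks = segment_bands(structural0.data.shape, surface_px, bands, dz_tissue)
    return bands, surface_px, dz_tissue, band_masks


def _run_quantify(config, scene, timecourse, angio_volumes, structural0,
                  timestamps, angio_geo, out_dir: Path, register) -> None:
    q = config.quantify
    bands, surface_px, dz_tissue, band_masks = _quantify_geometry(
        config, scene, structural0, angio_geo)
    baseline = timecourse.frames("baseline")
    base_mean = np.mean([angio_volumes[i] for i in baseline], axis=0)
    # large-vessel mask from the superficial band of the baseline angiogram
    band1 = band_masks[0]
    ef = np.where(band1, base_mean, 0.0).sum(axis=-1) / np.maximum(band1.sum(axis=-1), 1)
    vmask = make_vessel_mask(ef, q.vessel_mask_quantile, q.vessel_mask_min_area_px)
    static_region = _static_region_for_threshold(scene, band_masks)
    thr = noise_threshold(base_mean, static_region, q.threshold_k_sigma)
    series = total_flow_series(
        angio_volumes, band_masks, timestamps_s=timestamps,
        vessel_mask=vmask, threshold=thr, baseline_frames=baseline)
    series.to_csv(out_dir / "flow_timeseries.csv")
    register(out_dir / "flow_timeseries.csv")
    write_volume_tiff(out_dir / "vessel_mask.tif", vmask.mask.astype(np.float32)[None],
                      {"threshold_quantile": q.vessel_mask_quantile,
                       "min_area_px": q.vessel_mask_min_area_px})
    register(out_dir / "vessel_mask.tif")


def _static_region_for_threshold(scene, band_masks) -> np.ndarray:
    region = np.zeros_like(band_masks[0])
    for bm in band_masks:
        region |= bm
    return region & ~scene.vessel_columns()[:, :, None]


def _run_project(config, angio_volumes, structural0, angio_geo, out_dir: Path, register) -> None:
    from matplotlib import pyplot as plt

    pr = config.project
    dz_tissue = angio_geo["dz_air_um"] / angio_geo["refractive_index"]
    surface_px = detect_surface(structural0)
    for name, vol in (("baseline", angio_volumes[0]), ("final", angio_volumes[-1])):
        ef = enface(vol, pr.reduction)
        write_volume_tiff(out_dir / f"enface_{name}.tif", ef.data[None],
                          {"reduction": pr.reduction})
        register(out_dir / f"enface_{name}.tif")
        dc = depth_coded_angio(vol, surface_px, dz_tissue_um=dz_tissue,
                               depth_range_um=pr.depth_range_um, colormap=pr.colormap)
        plt.imsave(out_dir / f"depth_coded_{name}.png", np.clip(dc.rgb, 0, 1))
        register(out_dir / f"depth_coded_{name}.png")
    ef_s = enface(structural0.data, "mean")
    write_volume_tiff(out_dir / "enface_structural.tif", ef_s.data[None],
                      {"reduction": "mean"})
    register(out_dir / "enface_structural.tif")


def _run_infarct(config, out_dir: Path, register) -> None:
    ic = config.infarct
    spec = SectionStackSpec(
        n_sections=ic.n_sections, pixel_size_um=ic.pixel_size_um,
        slice_thickness_um=ic.slice_thickness_um, shape=ic.shape,
        max_shift_px=ic.max_shift_px, max_rot_deg=ic.max_rot_deg,
        noise_std=ic.noise_std)
    stack, truth_t, truth_label = simulate_sections(spec, config.seed)
    write_section_stack(out_dir / "sections.tif", stack)
    register(out_dir / "sections.tif")
    aligned, transforms = align_stack(stack)
    label = segment_infarct(aligned, ic.pixel_size_um, ic.slice_thickness_um,
                            threshold=ic.threshold)
    metrics = infarct_metrics(label, ic.hemisphere_mm3)
    write_label_nifti(out_dir / "infarct_label.nii.gz", label)
    (out_dir / "infarct_metrics.json").write_text(json.dumps({
        "volume_mm3": metrics.volume_mm3,
        "ap_length_mm": metrics.ap_length_mm,
        "ml_width_mm": metrics.ml_width_mm,
        "dv_height_mm": metrics.dv_height_mm,
        "percent_hemisphere": metrics.percent_hemisphere,
    }, indent=2))
    register(out_dir / "infarct_metrics.json")
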