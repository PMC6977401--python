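"""Hemodynamic quantification.

Depth-banded total-flow time series from angiographic volumes: the cortex is
split into three functional depth bands below the detected brain surface
(0-160 um meningeal vessels, 160-320 um penetrating arterioles, >320 um
capillaries), background noise is rejected by a threshold, large superficial
vessels are masked out, and the remaining motion signal is integrated per
band and per time point.  Follow-up sessions are rescaled by equalizing noise
levels and the depth-dependent structural intensity profile.  The module also
measures the limited-flow area fraction and classifies per-vessel reperfusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .angio import AngioVolume
from .recon import StructuralVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DepthBands:
    """Ordered, contiguous half-open depth intervals (um from brain surface)."""

    edges_um: tuple[float, ...] = (0.0, 160.0, 320.0, 640.0)

    def __post_init__(self) -> None:
        e = self.edges_um
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("band edges must be strictly increasing")
        if e[0] != 0.0:
            raise ValueError("bands must start at the surface (0 um)")

    @property
    def n_bands(self) -> int:
        return len(self.edges_um) - 1

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.edges_um, self.edges_um[1:]))

    @property
    def z_max_um(self) -> float:
        return self.edges_um[-1]


@dataclass
class VesselMask:
    """En face (Y, X) mask of large superficial vessels.

    Quantification keeps only the columns *not* in the mask (the inverted
    image of the large vessel)."""

    mask: np.ndarray
    threshold_quantile: float
    min_area_px: int

    def __post_init__(self) -> None:
        if self.mask.mean() >= 1.0:
            raise ValueError("vessel mask covers the whole field")


@dataclass
class FlowTimeSeries:
    """Integrated angiographic signal per depth band per time point."""

    table: pd.DataFrame  # time_s, band{i}_raw, band{i}_norm
    threshold: float
    baseline_frames: list[int]
    mask_id: str = ""

    @property
    def n_bands(self) -> int:
        return sum(c.startswith("band") and c.endswith("_raw") for c in self.table.columns)

    def band_norm(self, band: int) -> np.ndarray:
        return self.table[f"band{band}_norm"].to_numpy()

    def band_raw(self, band: int) -> np.ndarray:
        return self.table[f"band{band}_raw"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# surface detection and band segmentation
# ---------------------------------------------------------------------------

def detect_surface(
    structural: StructuralVolume | np.ndarray,
    *,
    smooth_sigma_z: float = 1.5,
    lateral_median: int = 3,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """Per-(Y, X) depth pixel of the brain surface.

    The volume is smoothed axially and median-filtered laterally; the surface
    is the first depth at which the smoothed intensity exceeds an adaptive
    threshold (a fraction of the bright-signal level above the dark floor).
    A-scans with no super-threshold sample are filled from their neighbours
    and flagged in the log.
    """
    data = structural.data if isinstance(structural, StructuralVolume) else np.asarray(structural)
    if not np.any(data > 0):
        raise ValueError("structural volume has no signal; surface undefined")
    sm = ndimage.gaussian_filter1d(data.astype(float), smooth_sigma_z, axis=-1)
    if lateral_median > 1:
        sm = ndimage.median_filter(sm, size=(lateral_median, lateral_median, 1))
    lo = np.quantile(sm, 0.05)
    hi = np.quantile(sm, 0.995)
    thr = lo + threshold_fraction * (hi - lo)
    above = sm > thr
    first = np.argmax(above, axis=-1).astype(float)
    invalid = ~above.any(axis=-1)
    if invalid.any():
        log.warning("surface undefined for %d A-scans; filling from neighbours",
                    int(invalid.sum()))
        first[invalid] = np.nan
        # iterative neighbourhood median fill
        while np.isnan(first).any():
            med = ndimage.generic_filter(first, np.nanmedian, size=3, mode="nearest")
            fill = np.isnan(first) & ~np.isnan(med)
            if not fill.any():
                first[np.isnan(first)] = np.nanmedian(first)
                break
            first[fill] = med[fill]
    return first


def segment_bands(
    volume_shape_or_volume,
    surface_px: np.ndarray,
    bands: DepthBands,
    dz_tissue_um: float,
) -> list[np.ndarray]:
    """Per-band boolean voxel masks on the reconstructed grid.

    Every voxel at non-negative depth below the local surface and above the
    deepest band edge belongs to exactly one band, assigned by half-open
    interval tests on ``(z - surface) * dz_tissue``.
    """
    if hasattr(volume_shape_or_volume, "data"):
        shape = volume_shape_or_volume.data.shape
    elif isinstance(volume_shape_or_volume, np.ndarray):
        shape = volume_shape_or_volume.shape
    else:
        shape = tuple(volume_shape_or_volume)
    nz = shape[-1]
    depth = (np.arange(nz)[None, None, :] - np.asarray(surface_px)[:, :, None]) * dz_tissue_um
    masks = []
    for lo, hi in bands.intervals:
        masks.append((depth >= lo) & (depth < hi))
    return masks


# ---------------------------------------------------------------------------
# masking and thresholding
# ---------------------------------------------------------------------------

def make_vessel_mask(
    enface_map: np.ndarray,
    threshold_quantile: float = 0.9,
    min_area_px: int = 50,
) -> VesselMask:
    """Large-vessel mask from a baseline en face angiogram: threshold at a
    quantile, keep connected components of at least ``min_area_px``."""
    if not (0.0 < threshold_quantile < 1.0):
        raise ValueError("threshold quantile must be in (0, 1)")
    m = np.asarray(enface_map, float)
    thr = np.quantile(m, threshold_quantile)
    binary = m > thr
    if not binary.any():
        log.warning("uniform en face map: empty vessel mask")
        return VesselMask(binary, threshold_quantile, min_area_px)
    labels = measure.label(binary)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area_px
    keep[0] = False
    cleaned = keep[labels]
    if not cleaned.any():
        log.info("no connected component reaches %d px; empty vessel mask", min_area_px)
    return VesselMask(cleaned, threshold_quantile, min_area_px)


def noise_threshold(angio: AngioVolume | np.ndarray, static_region: np.ndarray,
                    k_sigma: float = 5.0) -> float:
    """Background-rejection threshold: mean + k * SD of the motion signal over
    a declared static region."""
    data = angio.data if isinstance(angio, AngioVolume) else np.asarray(angio)
    vals = data[np.asarray(static_region, bool)]
    if vals.size == 0:
        raise ValueError("static region is empty")
    return float(vals.mean() + k_sigma * vals.std())


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def total_flow_series(
    angio_volumes,
    band_masks: list[np.ndarray],
    *,
    timestamps_s: np.ndarray | None = None,
    vessel_mask: VesselMask | np.ndarray | None = None,
    threshold: float = 0.0,
    baseline_frames: list[int] | None = None,
) -> FlowTimeSeries:
    """Integrate the thresholded, large-vessel-masked motion signal per band.

    Per volume: voxels below ``threshold`` are zeroed, columns under the
    large-vessel mask are zeroed, and the remaining intensity is summed over
    each band mask.  The normalized series divides each band by its mean over
    ``baseline_frames`` (default: the first frame).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vmask = None
    if vessel_mask is not None:
        vmask = vessel_mask.mask if isinstance(vessel_mask, VesselMask) else np.asarray(vessel_mask, bool)
    rows = []
    shape = None
    for vol in angio_volumes:
        data = vol.data if isinstance(vol, AngioVolume) else np.asarray(vol)
        if shape is None:
            shape = data.shape
            for bm in band_masks:
                if bm.shape != shape:
                    raise ValueError("band mask grid does not match volumes")
            if vmask is not None and vmask.shape != shape[:2]:
                raise ValueError("vessel mask grid does not match volumes")
        elif data.shape != shape:
            raise ValueError("volumes in the series have mismatched grids")
        kept = np.where(data >= threshold, data, 0.0)
        if vmask is not None:
            kept = np.where(vmask[:, :, None], 0.0, kept)
        rows.append([float(kept[bm].sum()) for bm in band_masks])
    raw = np.asarray(rows)  # (T, n_bands)
    n_t = raw.shape[0]
    if baseline_frames is None:
        baseline_frames = [0]
    base = raw[baseline_frames].mean(axis=0)
    if np.any(base == 0):
        norm = np.full_like(raw, np.nan)
        valid = base > 0
        norm[:, valid] = raw[:, valid] / base[valid]
        log.warning("zero baseline in %d band(s); normalized series undefined there",
                    int((~valid).sum()))
    else:
        norm = raw / base
    if timestamps_s is None:
        timestamps_s = np.arange(n_t, dtype=float)
    cols = {"time_s": np.asarray(timestamps_s, float)}
    for b in range(raw.shape[1]):
        cols[f"band{b + 1}_raw"] = raw[:, b]
    for b in range(raw.shape[1]):
        cols[f"band{b + 1}_norm"] = norm[:, b]
    return FlowTimeSeries(
        table=pd.DataFrame(cols),
        threshold=float(threshold),
        baseline_frames=list(baseline_frames),
    )


def normalize_sessions(
    angio_day0: np.ndarray,
    angio_day1: np.ndarray,
    structural_day0: np.ndarray,
    structural_day1: np.ndarray,
    noise_region: np.ndarray,
    *,
    smooth_sigma: float = 3.0,
    gain_clamp: tuple[float, float] = (0.2, 5.0),
) -> np.ndarray:
    """Scale a follow-up session onto the baseline session's intensity scale.

    The follow-up angiogram is multiplied globally by the ratio of the noise
    levels (median motion signal over the declared static region) and then by
    a per-depth gain, the ratio of the smoothed mean structural depth profiles
    (baseline / follow-up), compensating depth-dependent signal differences.
    Gains are clamped and clamping is logged.  Two identical sessions map to
    the identity.
    """
    a1 = np.asarray(angio_day1, float)
    s0 = np.asarray(structural_day0, float)
    s1 = np.asarray(structural_day1, float)
    nr = np.asarray(noise_region, bool)
    n0 = float(np.median(np.asarray(angio_day0)[nr]))
    n1 = float(np.median(a1[nr]))
    if n1 > 0:
        g_noise = n0 / n1
    else:
        g_noise = 1.0
        log.warning("zero follow-up noise level; skipping noise equalization")
    p0 = ndimage.gaussian_filter1d(s0.mean(axis=(0, 1)), smooth_sigma)
    p1 = ndimage.gaussian_filter1d(s1.mean(axis=(0, 1)), smooth_sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(p1 > 0, p0 / np.where(p1 > 0, p1, 1.0), 1.0)
    clamped = (gain < gain_clamp[0]) | (gain > gain_clamp[1])
    if clamped.any():
        log.warning("depth gain clamped at %d depths", int(clamped.sum()))
        gain = np.clip(gain, *gain_clamp)
    return a1 * g_noise * gain[None, None, :]


# ---------------------------------------------------------------------------
# area and reperfusion metrics
# ---------------------------------------------------------------------------

def limited_flow_area(
    enface_map: np.ndarray,
    roi: np.ndarray,
    threshold: float,
    baseline_map: np.ndarray | None = None,
) -> float:
    """Fraction of the positive-signal area with limited flow.

    Counts ROI pixels whose signal is below ``threshold`` among the ROI pixels
    with positive baseline signal (the baseline map defaults to the map
    itself, i.e. all ROI pixels with any signal history count).
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    m = np.asarray(enface_map, float)
    base = m if baseline_map is None else np.asarray(baseline_map, float)
    positive = roi & (base > 0)
    denom = int(positive.sum())
    if denom == 0:
        raise ValueError("no baseline-positive pixels in ROI")
    limited = int((positive & (m < threshold)).sum())
    return limited / denom


REPERFUSION_CLASSES = ("none", "partial", "full")


def classify_reperfusion(
    baseline: np.ndarray | float,
    followup: np.ndarray | float,
    c_none: float = 0.2,
    c_full: float = 0.8,
) -> np.ndarray | str:
    """Classify per-vessel reperfusion from the follow-up / baseline signal
    ratio: below ``c_none`` -> 'none', in [c_none, c_full) -> 'partial',
    at or above ``c_full`` -> 'full'."""
    if not (0.0 < c_none < c_full < 1.0 or (0 < c_none < c_full)):
        raise ValueError("need cut points 0 < c_none < c_full")
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    if np.any(b <= 0):
        raise ValueError("zero or negative baseline signal; ratio undefined")
    ratio = f / b
    cls = np.where(ratio < c_none, "none", np.where(ratio < c_full, "partial", "full"))
    if cls.ndim == 0:
        return str(cls)
    return cls


def reperfusion_summary(classes: np.ndarray) -> dict[str, float]:
    """Fraction of vessels (or animals) per reperfusion class."""
    classes = np.asarray(classes)
    n = classes.size
    return {c: float((classes == c).sum()) / n for c in REPERFUSION_CLASSES}
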