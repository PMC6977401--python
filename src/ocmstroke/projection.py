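"""En face projections, depth-coded angiographic maps and B-scan extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .angio import AngioVolume
from .recon import StructuralVolume

DEFAULT_DEPTH_RANGE_UM = (0.0, 640.0)
DEFAULT_COLORMAP = "turbo"


@dataclass
class EnFaceMap:
    """2-D (Y, X) depth-reduced field."""

    data: np.ndarray
    kind: str  # 'structural' | 'angio'
    reduction: str  # 'mean' | 'max'
    depth_interval_px: tuple[int, int]


@dataclass
class DepthCodedMap:
    """RGB en face image; hue encodes the depth of the dominant motion signal
    below the brain surface, brightness its magnitude."""

    rgb: np.ndarray  # (Y, X, 3) in [0, 1]
    depth_range_um: tuple[float, float]
    colormap: str

    def hue_for_depth(self, depth_um: float) -> np.ndarray:
        lo, hi = self.depth_range_um
        t = np.clip((depth_um - lo) / (hi - lo), 0.0, 1.0)
        return np.asarray(colormaps[self.colormap](t))[:3]


def _volume_data(volume) -> np.ndarray:
    if isinstance(volume, (AngioVolume, StructuralVolume)):
        return volume.data
    return np.asarray(volume)


def enface(volume, reduction: str = "mean",
           depth_interval: tuple[int, int] | None = None,
           kind: str = "angio") -> EnFaceMap:
    """Reduce a (Y, X, Z) volume over a half-open depth-pixel interval.

    The mean reduction is the default (flattening by the mean intensity value
    of each A-scan); max projection is available for conventional angiogram
    rendering.
    """
    data = _volume_data(volume)
    nz = data.shape[-1]
    if depth_interval is None:
        depth_interval = (0, nz)
    a, b = depth_interval
    if not (0 <= a < b <= nz):
        raise ValueError(f"empty or out-of-range depth interval {depth_interval}")
    sl = data[..., a:b]
    if reduction == "mean":
        red = sl.mean(axis=-1)
    elif reduction == "max":
        red = sl.max(axis=-1)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return EnFaceMap(data=red, kind=kind, reduction=reduction, depth_interval_px=(a, b))


def depth_coded_angio(
    angio: AngioVolume | np.ndarray,
    surface_px: np.ndarray,
    *,
    dz_tissue_um: float | None = None,
    depth_range_um: tuple[float, float] = DEFAULT_DEPTH_RANGE_UM,
    colormap: str = DEFAULT_COLORMAP,
    brightness_quantile: float = 0.999,
) -> DepthCodedMap:
    """False-color the depth of each pixel's dominant angiographic signal.

    Per (Y, X): the depth (relative to the local surface, in tissue microns)
    of the maximum motion signal selects the hue; the signal magnitude,
    normalized to a high quantile, sets the brightness.  A zero volume yields
    a black image.
    """
    data = _volume_data(angio)
    if dz_tissue_um is None:
        dz_tissue_um = angio.dz_tissue_um if isinstance(angio, AngioVolume) else 1.0
    zmax = np.argmax(data, axis=-1)
    peak = np.take_along_axis(data, zmax[..., None], axis=-1)[..., 0]
    depth_um = (zmax - np.asarray(surface_px)) * dz_tissue_um
    lo, hi = depth_range_um
    t = np.clip((depth_um - lo) / (hi - lo), 0.0, 1.0)
    hue = np.asarray(colormaps[colormap](t))[..., :3]
    ref = np.quantile(peak, brightness_quantile)
    bright = peak / ref if ref > 0 else np.zeros_like(peak)
    rgb = hue * np.clip(bright, 0.0, 1.0)[..., None]
    return DepthCodedMap(rgb=rgb, depth_range_um=depth_range_um, colormap=colormap)


def extract_bscan(volume, y: int) -> np.ndarray:
    """Exact (X, Z) slice at slow-axis index ``y``; no resampling."""
    data = _volume_data(volume)
    if not (0 <= y < data.shape[0]):
        raise IndexError(f"y index {y} out of range [0, {data.shape[0]})")
    return data[y]
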