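"""Serial-section 3-D infarct reconstruction and volumetry.

Sections are preprocessed (8-bit, inverted, contrast-stretched, downsampled
to 20 um/px, 2x2 lower-median filtered), sequentially rigidly aligned from
the middle of the stack toward either end with normalized cross-correlation
as the similarity metric, segmented into a boolean lesion volume, and
measured: volume, anterior-posterior length, medio-lateral width,
dorso-ventral height, and percent of a hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from skimage.registration import phase_cross_correlation

from .sections import SectionStack, apply_rigid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotation about the image centre (degrees,
    counter-clockwise, in (-180, 180]) followed by a pixel translation."""

    rotation_deg: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.rotation_deg, self.dx, self.dy])):
            raise ValueError("transform parameters must be finite")
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation must lie in (-180, 180]")

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        return apply_rigid(image, self.dx, self.dy, self.rotation_deg, order=order)

    @property
    def identity_like(self) -> bool:
        return abs(self.rotation_deg) < 1e-9 and abs(self.dx) < 1e-9 and abs(self.dy) < 1e-9


@dataclass
class LabelVolume:
    """Boolean lesion volume on the aligned grid."""

    data: np.ndarray  # (sections, rows, cols)
    pixel_size_um: float
    slice_thickness_um: float

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.pixel_size_um ** 2 * self.slice_thickness_um) * 1e-9

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class InfarctMetrics:
    volume_mm3: float
    ap_length_mm: float
    ml_width_mm: float
    dv_height_mm: float
    percent_hemisphere: float


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_section(
    image: np.ndarray,
    pixel_size_um: float,
    target_um: float = 20.0,
    *,
    invert: bool = True,
    contrast_percentiles: tuple[float, float] = (1.0, 99.0),
    median_size: int = 2,
) -> np.ndarray:
    """Microscope image -> analysis-ready 8-bit section.

    Rescale to 8 bit, optionally invert to negative, percentile contrast
    stretch, area-average downsample to the target pitch, and smooth with a
    square median filter (lower median for even windows, where the classic
    2x2 window has no unique median).  A constant image skips the stretch
    (flagged) and is returned constant.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    factor = target_um / pixel_size_um
    if factor > min(img.shape):
        raise ValueError("target pixel size coarser than the image extent")

    vmax = img.max()
    v = img / vmax * 255.0 if vmax > 0 else img
    if invert:
        v = 255.0 - v
    lo, hi = np.percentile(v, contrast_percentiles)
    if hi > lo:
        v = np.clip((v - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    else:
        log.warning("constant image: contrast stretch skipped")

    if factor != 1.0:
        if abs(factor - round(factor)) < 1e-9 and factor >= 1:
            f = int(round(factor))
            h, w = (img.shape[0] // f) * f, (img.shape[1] // f) * f
            v = v[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))
        else:
            zoom = 1.0 / factor
            v = ndimage.zoom(v, zoom, order=1)
    if median_size > 1:
        if median_size % 2 == 0:
            # rank filter at the lower median for even windows
            v = ndimage.rank_filter(v, rank=median_size ** 2 // 2 - 1,
                                    size=median_size)
        else:
            v = ndimage.median_filter(v, size=median_size)
    return np.clip(np.round(v), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    *,
    rot_range_deg: float = 15.0,
    rot_step_deg: float = 1.0,
    rot_fine_deg: float = 0.1,
    upsample: int = 20,
) -> RigidTransform2D:
    """Rigid transform maximizing normalized cross-correlation.

    Coarse-to-fine exhaustive rotation search; at each candidate rotation the
    translation comes from the sub-pixel Fourier cross-correlation peak and
    the candidate is scored by NCC after shifting.  The best fine-grid angle
    is refined by a quadratic fit through its neighbours.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("flat (zero-variance) image cannot be registered")

    def score(ang: float) -> float:
        rot = apply_rigid(moving, 0.0, 0.0, ang)
        shift, _, _ = phase_cross_correlation(fixed, rot, upsample_factor=10,
                                              normalization=None)
        return _ncc(fixed, ndimage.shift(rot, shift, order=1, mode="constant", cval=0.0))

    coarse = np.arange(-rot_range_deg, rot_range_deg + rot_step_deg / 2, rot_step_deg)
    best = coarse[int(np.argmax([score(a) for a in coarse]))]
    fine = np.arange(best - rot_step_deg, best + rot_step_deg + rot_fine_deg / 2,
                     rot_fine_deg)
    fine_scores = [score(a) for a in fine]
    i = int(np.argmax(fine_scores))
    ang = fine[i]
    if 0 < i < len(fine) - 1:
        y0, y1, y2 = fine_scores[i - 1], fine_scores[i], fine_scores[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            ang = ang + 0.5 * (y0 - y2) / denom * rot_fine_deg
    rot = apply_rigid(moving, 0.0, 0.0, ang)
    shift, _, _ = phase_cross_correlation(fixed, rot, upsample_factor=upsample,
                                          normalization=None)
    return RigidTransform2D(rotation_deg=float(ang), dx=float(shift[1]), dy=float(shift[0]))


def align_stack(
    stack: SectionStack | np.ndarray,
    *,
    rot_range_deg: float = 15.0,
    rot_step_deg: float = 0.5,
) -> tuple[np.ndarray, list[RigidTransform2D]]:
    """Middle-out sequential rigid alignment.

    The middle section (lower middle for even counts) is the fixed reference;
    each neighbour is registered to its already-aligned inner neighbour and
    the recovered transforms accumulate outward.  Returns the aligned images
    and the per-section transforms (identity at the reference).
    """
    images = stack.images if isinstance(stack, SectionStack) else np.asarray(stack, float)
    n = images.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sections")
    mid = (n - 1) // 2
    aligned = np.empty_like(images, dtype=float)
    transforms: list[RigidTransform2D | None] = [None] * n
    aligned[mid] = images[mid]
    transforms[mid] = RigidTransform2D(0.0, 0.0, 0.0)
    for direction in (1, -1):
        i = mid + direction
        while 0 <= i < n:
            try:
                t = register_pair(aligned[i - direction], images[i],
                                  rot_range_deg=rot_range_deg,
                                  rot_step_deg=rot_step_deg)
            except ValueError as exc:
                raise RuntimeError(f"registration failed at section {i}: {exc}") from exc
            aligned[i] = t.apply(images[i])
            transforms[i] = t
            i += direction
    return aligned, transforms  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# segmentation and metrics
# ---------------------------------------------------------------------------

def segment_infarct(
    aligned: np.ndarray,
    pixel_size_um: float,
    slice_thickness_um: float,
    *,
    threshold: str | float = "otsu",
    bright_lesion: bool = True,
    user_mask: np.ndarray | None = None,
    keep_largest: bool = True,
) -> LabelVolume:
    """Threshold the aligned stack into a boolean lesion volume.

    ``threshold='otsu'`` (default) computes one Otsu threshold over the whole
    stack; a float gives a fixed threshold.  The largest connected 3-D
    component is kept.  A user-supplied mask is honoured verbatim, replacing
    the automatic step.
    """
    aligned = np.asarray(aligned)
    if user_mask is not None:
        mask = np.asarray(user_mask, bool)
        if mask.shape != aligned.shape:
            raise ValueError("user mask shape does not match stack")
        return LabelVolume(mask.copy(), pixel_size_um, slice_thickness_um)
    data = aligned.astype(float)
    if not bright_lesion:
        data = data.max() - data
    if threshold == "otsu":
        thr = filters.threshold_otsu(data)
    else:
        thr = float(threshold)
    mask = data > thr
    if not mask.any():
        log.warning("no foreground found; empty label volume")
        return LabelVolume(mask, pixel_size_um, slice_thickness_um)
    if keep_largest:
        labels = measure.label(mask, connectivity=3)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return LabelVolume(mask, pixel_size_um, slice_thickness_um)


def infarct_metrics(label: LabelVolume, hemisphere_mm3: float = 127.3) -> InfarctMetrics:
    """Volume and bounding extents of the lesion.

    Volume is voxel count x pixel area x slice thickness.  The AP length is
    the number of occupied sections times the thickness; ML width and DV
    height are bounding-box spans times the pixel size.  The hemisphere
    volume (default 127.3 mm^3, chosen so that a 1.4 mm^3 lesion corresponds
    to 1.1% of a hemisphere) converts volume to a percentage.
    """
    if hemisphere_mm3 <= 0:
        raise ValueError("hemisphere volume must be positive")
    vol = label.n_voxels * label.voxel_volume_mm3
    if label.n_voxels == 0:
        return InfarctMetrics(0.0, 0.0, 0.0, 0.0, 0.0)
    occ = np.nonzero(label.data.any(axis=(1, 2)))[0]
    rows = np.nonzero(label.data.any(axis=(0, 2)))[0]
    cols = np.nonzero(label.data.any(axis=(0, 1)))[0]
    ap = occ.size * label.slice_thickness_um * 1e-3
    dv = (rows[-1] - rows[0] + 1) * label.pixel_size_um * 1e-3
    ml = (cols[-1] - cols[0] + 1) * label.pixel_size_um * 1e-3
    return InfarctMetrics(
        volume_mm3=vol,
        ap_length_mm=ap,
        ml_width_mm=ml,
        dv_height_mm=dv,
        percent_hemisphere=100.0 * vol / hemisphere_mm3,
    )
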