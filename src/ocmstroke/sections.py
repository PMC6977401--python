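"""Synthetic serial-section stacks with known misalignments.

Emulates a series of coronal fluorescence-microscopy images of 40-um
sections through a lesioned hemisphere: a bright lesion (union of ellipsoid
lobes) on a textured tissue background, each section displaced by a known
rigid offset and degraded by noise.  Ground truth — the per-section
transforms and the voxelized lesion — is returned alongside, so registration
and volumetry can be tested by recovery.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy import ndimage


class EllipsoidLobe(BaseModel):
    """One lesion lobe: centre and semi-axes in mm, axes (AP, ML, DV).

    AP is the stacking (coronal) axis; ML and DV are in-plane."""

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)


#: two-lobed default lesion: two partially separated, connected lobes side by
#: side along the medio-lateral axis; overall extent 1.1 (AP) x 2.4 (ML) x
#: 1.4 (DV) mm and volume ~1.4 mm^3 (~1.1% of a 127.3 mm^3 hemisphere),
#: mirroring the morphology of the reconstructed photothrombotic infarct
DEFAULT_LOBES = (
    EllipsoidLobe(center_mm=(0.0, -0.48, -0.20), semi_mm=(0.55, 0.72, 0.50)),
    EllipsoidLobe(center_mm=(0.0, 0.48, 0.30), semi_mm=(0.50, 0.72, 0.40)),
)


class SectionStackSpec(BaseModel):
    """Parameters of one synthetic section series."""

    n_sections: int = Field(29, ge=3)
    slice_thickness_um: float = Field(40.0, gt=0)
    pixel_size_um: float = Field(20.0, gt=0)
    shape: tuple[int, int] = (160, 160)  # (rows = DV, cols = ML)
    lobes: tuple[EllipsoidLobe, ...] = DEFAULT_LOBES
    offsets: tuple[tuple[float, float, float], ...] | None = None  # (dx, dy, deg)
    max_shift_px: float = 8.0
    max_rot_deg: float = 5.0
    zero_middle: bool = True  # keep the reference section unshifted
    noise_std: float = 0.02
    lesion_intensity: float = 0.6
    tissue_intensity: float = 0.25
    tissue_texture: float = 0.05

    @field_validator("offsets")
    @classmethod
    def _finite(cls, v):
        if v is not None and not np.all(np.isfinite(np.asarray(v, float))):
            raise ValueError("offsets must be finite")
        return v


class SectionStack:
    """Ordered grayscale section images with physical metadata."""

    def __init__(self, images: np.ndarray, pixel_size_um: float,
                 slice_thickness_um: float,
                 true_transforms: np.ndarray | None = None) -> None:
        images = np.asarray(images)
        if images.ndim != 3:
            raise ValueError("expected a (sections, rows, cols) array")
        self.images = images
        self.pixel_size_um = float(pixel_size_um)
        self.slice_thickness_um = float(slice_thickness_um)
        self.true_transforms = true_transforms  # (n, 3): dx, dy, deg

    def __len__(self) -> int:
        return self.images.shape[0]


def _lesion_section_mask(spec: SectionStackSpec, section: int) -> np.ndarray:
    """Boolean lesion cross-section of one z-slab (evaluated at mid-slab)."""
    n, h, w = spec.n_sections, *spec.shape
    px_mm = spec.pixel_size_um / 1e3
    th_mm = spec.slice_thickness_um / 1e3
    ap = (section - (n - 1) / 2.0) * th_mm
    dv = (np.arange(h) - (h - 1) / 2.0) * px_mm
    ml = (np.arange(w) - (w - 1) / 2.0) * px_mm
    mask = np.zeros((h, w), bool)
    for lobe in spec.lobes:
        ca, cm, cd = lobe.center_mm
        sa, sm, sd = lobe.semi_mm
        q = ((ap - ca) / sa) ** 2
        if q >= 1.0:
            continue
        mask |= (((dv[:, None] - cd) / sd) ** 2 + ((ml[None, :] - cm) / sm) ** 2) <= (1.0 - q)
    return mask


def _tissue_background(spec: SectionStackSpec, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying tissue texture, correlated across neighbouring sections."""
    n, h, w = spec.n_sections, *spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue = (((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.46 * w)) ** 2) <= 1.0
    if spec.tissue_texture > 0:
        noise = rng.normal(0.0, 1.0, (n, h, w))
        texture = ndimage.gaussian_filter(noise, sigma=(1.5, 4.0, 4.0))
        texture *= spec.tissue_texture / max(texture.std(), 1e-12)
    else:
        texture = np.zeros((n, h, w))
    return tissue[None, :, :] * (spec.tissue_intensity + texture)


def apply_rigid(image: np.ndarray, dx: float, dy: float, deg: float,
                order: int = 1) -> np.ndarray:
    """Rotate about the image centre then translate by (dx, dy) pixels
    (x = columns, y = rows); bilinear interpolation, zero padding."""
    out = image
    if deg:
        out = ndimage.rotate(out, deg, reshape=False, order=order, mode="constant", cval=0.0)
    if dx or dy:
        out = ndimage.shift(out, (dy, dx), order=order, mode="constant", cval=0.0)
    return out


def simulate_sections(spec: SectionStackSpec, seed: int):
    """Generate a misaligned section stack plus ground truth.

    Returns ``(stack, true_transforms, label_volume)`` where
    ``true_transforms`` is an (n, 3) array of per-section (dx, dy, deg)
    offsets applied to the clean sections and ``label_volume`` the boolean
    lesion rasterization in the clean (aligned) frame.
    """
    rng = np.random.default_rng([seed, 31])
    n, h, w = spec.n_sections, *spec.shape

    if spec.offsets is not None:
        if len(spec.offsets) != n:
            raise ValueError("offsets length does not match n_sections")
        offsets = np.asarray(spec.offsets, float)
    else:
        offsets = np.stack([
            rng.uniform(-spec.max_shift_px, spec.max_shift_px, n),
            rng.uniform(-spec.max_shift_px, spec.max_shift_px, n),
            rng.uniform(-spec.max_rot_deg, spec.max_rot_deg, n),
        ], axis=1)
        if spec.zero_middle:
            # keep the reference (middle) section in the clean frame so the
            # recovered alignment is directly comparable to ground truth
            offsets[(n - 1) // 2] = 0.0

    background = _tissue_background(spec, rng)
    label = np.zeros((n, h, w), bool)
    images = np.empty((n, h, w), np.float32)
    for s in range(n):
        mask = _lesion_section_mask(spec, s)
        label[s] = mask
        clean = background[s] + spec.lesion_intensity * mask
        dx, dy, deg = offsets[s]
        moved = apply_rigid(clean, dx, dy, deg)
        if mask.any():
            lesion_moved = apply_rigid(mask.astype(float), dx, dy, deg)
            if lesion_moved.max() < 0.5:
                raise ValueError(f"section {s}: offsets push the lesion out of frame")
        if spec.noise_std > 0:
            moved = moved + rng.normal(0.0, spec.noise_std, (h, w))
        images[s] = np.clip(moved, 0.0, 1.0)

    stack = SectionStack(images, spec.pixel_size_um, spec.slice_thickness_um,
                         true_transforms=offsets)
    return stack, offsets, label
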