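"""File formats: HDF5 spectral series, multi-page TIFF volumes and stacks
with JSON sidecars, NIfTI label volumes, CSV time series."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .forward import SpectralSeries
from .infarct import LabelVolume, RigidTransform2D
from .protocol import AcquisitionProtocol
from .sections import SectionStack


# ---------------------------------------------------------------------------
# spectral series (HDF5)
# ---------------------------------------------------------------------------

def write_spectral_series(path, series: SpectralSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=series.data, compression="gzip", compression_opts=1)
        f.create_dataset("k_grid", data=series.wavenumber_grid)
        f.create_dataset("timestamps", data=series.timestamps_s)
        f.create_dataset("dispersion_truth", data=series.dispersion_truth)
        f.attrs["protocol"] = series.protocol.model_dump_json()
        f.attrs["frame_index"] = series.frame_index


def read_spectral_series(path) -> SpectralSeries:
    with h5py.File(path, "r") as f:
        protocol = AcquisitionProtocol.model_validate_json(f.attrs["protocol"])
        series = SpectralSeries(
            data=f["spectra"][...],
            wavenumber_grid=f["k_grid"][...],
            timestamps_s=f["timestamps"][...],
            protocol=protocol,
            dispersion_truth=f["dispersion_truth"][...],
            frame_index=int(f.attrs.get("frame_index", 0)),
        )
    series.validate()
    return series


# ---------------------------------------------------------------------------
# volumes (multi-page TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def write_volume_tiff(path, data: np.ndarray, meta: dict | None = None) -> None:
    """Write a (Y, X, Z) or (pages, H, W) array as 32-bit multi-page TIFF.

    (Y, X, Z) volumes are stored Z-major (one en face page per depth)."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 3:
        pages = np.moveaxis(arr, -1, 0).astype(np.float32)
    else:
        pages = arr.astype(np.float32)[None]
    tifffile.imwrite(path, pages)
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_volume_tiff(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    if pages.ndim == 3:
        return np.moveaxis(pages, 0, -1), meta
    return pages, meta


# ---------------------------------------------------------------------------
# section stacks
# ---------------------------------------------------------------------------

def write_section_stack(path, stack: SectionStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.images))
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "slice_thickness_um": stack.slice_thickness_um,
    }
    if stack.true_transforms is not None:
        meta["true_transforms"] = np.asarray(stack.true_transforms).tolist()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_section_stack(path) -> SectionStack:
    path = Path(path)
    images = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    tt = meta.get("true_transforms")
    return SectionStack(
        images,
        pixel_size_um=meta["pixel_size_um"],
        slice_thickness_um=meta["slice_thickness_um"],
        true_transforms=np.asarray(tt) if tt is not None else None,
    )


def write_transforms_json(path, transforms: list[RigidTransform2D]) -> None:
    Path(path).write_text(json.dumps(
        [{"rotation_deg": t.rotation_deg, "dx": t.dx, "dy": t.dy} for t in transforms],
        indent=2))


# ---------------------------------------------------------------------------
# label volumes (NIfTI)
# ---------------------------------------------------------------------------

def write_label_nifti(path, label: LabelVolume) -> None:
    affine = np.diag([
        label.slice_thickness_um * 1e-3,
        label.pixel_size_um * 1e-3,
        label.pixel_size_um * 1e-3,
        1.0,
    ])
    img = nib.Nifti1Image(label.data.astype(np.uint8), affine)
    nib.save(img, str(path))
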