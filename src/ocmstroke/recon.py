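"""Initial processing of raw spectra into complex and structural volumes.

Per spectrum: resample onto a uniform wavenumber grid, remove residual
dispersion by multiplying with the conjugate phase polynomial, apodize
(Hann by default), Fourier transform, keep the positive-frequency half and
crop to the depth interval of interest.  Structural volumes are the magnitude
of the complex mean over the oversampling (repeat) set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .forward import SpectralSeries, dispersion_phase

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationProfile:
    """Spectrometer calibration: uniform-k resampling map + dispersion phase.

    ``k_resample_map[j]`` is the fractional source-pixel index at which the
    j-th uniform-k output sample lives; ``dispersion_coeffs`` are the
    polynomial phase coefficients (quadratic term first) removed as
    ``exp(-i * phi(k))``.
    """

    k_resample_map: np.ndarray
    dispersion_coeffs: np.ndarray
    k_uniform: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.k_resample_map, float)
        if np.any(np.diff(m) <= 0):
            raise ValueError("k resample map must be monotone increasing")
        if not np.all(np.isfinite(np.asarray(self.dispersion_coeffs, float))):
            raise ValueError("dispersion coefficients must be finite")

    @classmethod
    def identity(cls, n_spectral: int, dispersion_coeffs=()) -> "CalibrationProfile":
        return cls(np.arange(n_spectral, dtype=float), np.asarray(dispersion_coeffs, float))

    @classmethod
    def from_series(cls, series: SpectralSeries) -> "CalibrationProfile":
        """Calibration from simulator truth: resample the recorded grid onto
        the uniform grid with the same endpoints, compensate the dispersion
        that was synthesized in."""
        k = series.wavenumber_grid
        if np.any(np.diff(k) <= 0):
            raise ValueError("recorded wavenumber grid must be monotone")
        ku = np.linspace(k[0], k[-1], k.size)
        mapping = np.interp(ku, k, np.arange(k.size, dtype=float))
        return cls(mapping, np.asarray(series.dispersion_truth, float), k_uniform=ku)


@dataclass
class ComplexVolume:
    """Complex A-scan stack (Y, repeat, X, Z) after FFT and Z-cropping."""

    data: np.ndarray
    dz_air_um: float
    dx_um: float
    dy_um: float
    z_crop: tuple[int, int]  # half-open retained depth-pixel interval
    refractive_index: float = 1.35

    @property
    def dz_tissue_um(self) -> float:
        return self.dz_air_um / self.refractive_index

    @property
    def n_repeats(self) -> int:
        return self.data.shape[1]


@dataclass
class StructuralVolume:
    """Non-negative scattering intensity (Y, X, Z)."""

    data: np.ndarray
    dz_air_um: float
    dx_um: float
    dy_um: float
    z_crop: tuple[int, int]
    refractive_index: float = 1.35
    provenance: str = "coherent mean over repeats"

    @property
    def dz_tissue_um(self) -> float:
        return self.dz_air_um / self.refractive_index


# ---------------------------------------------------------------------------
# per-spectrum operations
# ---------------------------------------------------------------------------

def linearize_k(spectrum: np.ndarray, calibration: CalibrationProfile,
                interpolation: str = "cubic") -> np.ndarray:
    """Resample spectra (last axis) onto the uniform wavenumber grid.

    With an identity map the output equals the input exactly (spline knots are
    interpolated exactly).  Constant spectra are preserved by both kinds.
    """
    m = calibration.k_resample_map
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] != m.size:
        raise ValueError("spectrum length does not match calibration")
    x = np.arange(m.size, dtype=float)
    if np.max(np.abs(m - x)) < 1e-9:
        return spectrum.astype(float, copy=True) if spectrum.dtype.kind != "c" else spectrum.copy()
    if interpolation == "cubic":
        return CubicSpline(x, spectrum, axis=-1)(m)
    if interpolation == "linear":
        flat = spectrum.reshape(-1, m.size)
        out = np.empty_like(flat, dtype=float)
        for i, row in enumerate(flat):
            out[i] = np.interp(m, x, row)
        return out.reshape(spectrum.shape)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def compensate_dispersion(spectrum: np.ndarray, coeffs, k: np.ndarray | None = None,
                          n_spectral: int | None = None) -> np.ndarray:
    """Multiply by the conjugate dispersion phase ``exp(-i phi(k))``.

    ``k`` defaults to a symmetric normalized grid over the spectrum length.
    Real input is promoted to complex; zero coefficients return the input
    unchanged (as complex).
    """
    spectrum = np.asarray(spectrum)
    n = spectrum.shape[-1] if n_spectral is None else n_spectral
    if k is None:
        k = np.linspace(-1.0, 1.0, n)
    phi = dispersion_phase(k, np.asarray(coeffs, float) if coeffs is not None else None)
    return spectrum * np.exp(-1j * phi)


def spectral_window(n: int, kind: str | None = "hann") -> np.ndarray:
    if kind is None or kind == "none":
        return np.ones(n)
    if kind == "hann":
        return np.hanning(n)
    raise ValueError(f"unknown window {kind!r}")


# ---------------------------------------------------------------------------
# series reconstruction
# ---------------------------------------------------------------------------

def reconstruct_series(
    series: SpectralSeries,
    calibration: CalibrationProfile,
    z_crop: tuple[int, int] | None = None,
    *,
    window: str | None = "hann",
    interpolation: str = "cubic",
    dc_subtract: bool = True,
    tilt_correct: bool = False,
    keep: str = "positive",
    refractive_index: float = 1.35,
    out_dtype=np.complex64,
) -> ComplexVolume:
    """Raw 4-D spectra -> complex volume (Y, repeat, X, Z).

    ``keep='full'`` retains the whole FFT (both frequency halves, no crop);
    it exists for energy-conservation checks.  ``z_crop`` is a half-open
    depth-pixel interval within [0, n_spectral/2).
    """
    p = series.protocol
    n = p.n_spectral
    nd = n // 2
    if z_crop is None:
        z_crop = (0, nd)
    z0, z1 = z_crop
    if not (0 <= z0 < z1 <= nd):
        raise ValueError(f"z crop {z_crop} outside [0, {nd})")

    w = spectral_window(n, window)
    out = None
    for y in range(p.n_y):
        spec = series.data[y].astype(float)  # (R, X, N)
        if dc_subtract:
            spec = spec - spec.mean(axis=1, keepdims=True)
        spec = linearize_k(spec, calibration, interpolation)
        cplx = compensate_dispersion(spec, calibration.dispersion_coeffs)
        cplx *= w
        ascans = np.fft.fft(cplx, axis=-1, norm="ortho")
        if keep == "full":
            sl = ascans
        else:
            sl = ascans[..., z0:z1]
        if out is None:
            out = np.empty((p.n_y,) + sl.shape, out_dtype)
        out[y] = sl.astype(out_dtype)

    vol = ComplexVolume(
        data=out,
        dz_air_um=p.dz_air_um,
        dx_um=p.dx_um,
        dy_um=p.dy_um,
        z_crop=(0, out.shape[-1]) if keep == "full" else (z0, z1),
        refractive_index=refractive_index,
    )
    if tilt_correct and keep != "full":
        vol = correct_tilt(vol)
    return vol


def crop_z(volume: ComplexVolume, interval: tuple[int, int]) -> ComplexVolume:
    """Crop to a half-open interval given in the volume's own Z indexing.

    Nested crops compose to the crop by the intersection.
    """
    a, b = interval
    nz = volume.data.shape[-1]
    a2, b2 = max(a, 0), min(b, nz)
    if a2 >= b2:
        raise ValueError(f"empty crop interval {interval}")
    return replace(volume, data=volume.data[..., a2:b2],
                   z_crop=(volume.z_crop[0] + a2, volume.z_crop[0] + b2))


def detect_interface(volume: ComplexVolume) -> np.ndarray:
    """Per-A-scan depth index of the brightest reflection (Y, X)."""
    mag = np.abs(volume.data).mean(axis=1)  # (Y, X, Z)
    return np.argmax(mag, axis=-1)


def correct_tilt(volume: ComplexVolume) -> ComplexVolume:
    """Remove a planar sample tilt by integer axial rolls.

    A plane is least-squares fitted through the brightest-interface depth of
    every A-scan; each A-scan is rolled so the fitted plane becomes flat at
    its mean depth.
    """
    iface = detect_interface(volume)
    ny, nx = iface.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    A = np.stack([yy.ravel(), xx.ravel(), np.ones(yy.size)], axis=1)
    coef, *_ = np.linalg.lstsq(A, iface.ravel().astype(float), rcond=None)
    plane = (A @ coef).reshape(ny, nx)
    shift = np.round(plane - plane.mean()).astype(int)
    data = volume.data.copy()
    for y in range(ny):
        for x in range(nx):
            if shift[y, x]:
                data[y, :, x, :] = np.roll(data[y, :, x, :], -shift[y, x], axis=-1)
    return replace(volume, data=data)


def structural_volume(volume: ComplexVolume, mode: str = "coherent") -> StructuralVolume:
    """Collapse the repeat axis into a structural image.

    ``coherent`` (default): magnitude of the complex mean over repeats —
    static, noise-free repeats give the single-repeat magnitude, while
    decorrelated (flow) voxels average down.  ``incoherent``: mean of
    magnitudes, kept for comparison.
    """
    if volume.data.shape[1] < 1:
        raise ValueError("repeat axis must have length >= 1")
    if mode == "coherent":
        data = np.abs(volume.data.mean(axis=1))
    elif mode == "incoherent":
        data = np.abs(volume.data).mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StructuralVolume(
        data=data.astype(np.float32),
        dz_air_um=volume.dz_air_um,
        dx_um=volume.dx_um,
        dy_um=volume.dy_um,
        z_crop=volume.z_crop,
        refractive_index=volume.refractive_index,
        provenance=f"{mode} mean over {volume.data.shape[1]} repeats",
    )


# ---------------------------------------------------------------------------
# measurement helpers
# ---------------------------------------------------------------------------

def axial_peak(profile: np.ndarray, pad: int = 16) -> tuple[float, float]:
    """(peak position, FWHM) of a complex axial point response, both in depth
    pixels, measured on the Fourier-upsampled magnitude."""
    profile = np.asarray(profile)
    n = profile.shape[-1]
    spec = np.fft.ifft(profile)
    padded = np.zeros(n * pad, complex)
    padded[: n // 2] = spec[: n // 2]
    padded[-(n - n // 2):] = spec[n // 2:]
    mag = np.abs(np.fft.fft(padded))
    i = int(np.argmax(mag))
    half = mag[i] / 2.0
    lo = i
    while lo > 0 and mag[lo] > half:
        lo -= 1
    hi = i
    while hi < mag.size - 1 and mag[hi] > half:
        hi += 1
    # linear interpolation of the half-max crossings
    if mag[lo + 1] != mag[lo]:
        left = lo + (half - mag[lo]) / (mag[lo + 1] - mag[lo])
    else:
        left = float(lo)
    if mag[hi - 1] != mag[hi]:
        right = (hi - 1) + (mag[hi - 1] - half) / (mag[hi - 1] - mag[hi])
    else:
        right = float(hi)
    return i / pad, (right - left) / pad
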