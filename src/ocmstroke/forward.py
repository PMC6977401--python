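"""Fourier-domain OCM forward model.

Raw data are synthesized as discrete-scatterer spectral interferograms: each
A-scan spectrum is a Gaussian source envelope carrying one cosine fringe per
scatterer at optical path ``2 * z_opt`` (``z_opt`` = air-equivalent depth),
plus a polynomial dispersion phase, a per-repeat global bulk-motion phase, and
additive Gaussian noise (a shot-noise stand-in).  Scatterers in perfused
vessel voxels undergo an axial random walk between repeats, decorrelating the
phasor; static tissue keeps identical scatterers across the repeat set and
across the whole time series.

Flow model: a vessel's perfusion factor in [0, 1] is the probability that a
given vessel scatterer is mobile during one volumetric acquisition; mobile
scatterers step with an axial displacement scale set by the vessel's flow
class.  Because every flow class fully decorrelates the phasor at the source
wavenumber, the expected integrated motion signal of a vessel bed is
proportional to its perfusion factor, mirroring reduced red-blood-cell flux
under occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, protocol_timing
from .scene import Scene, StrokeTimecourse

#: central wavenumber (rad/um) of the 795 nm source
K_CENTER_UM = 2 * np.pi / 0.795

#: Gaussian envelope width as a fraction of the spectral span
ENVELOPE_WIDTH_FRAC = 0.35

DC_LEVEL = 1.0


# ---------------------------------------------------------------------------
# wavenumber grids
# ---------------------------------------------------------------------------

def uniform_k_grid(n_spectral: int, z_range_air_um: float,
                   k_center: float = K_CENTER_UM) -> np.ndarray:
    """Uniform wavenumber grid whose FFT depth pitch is
    ``z_range_air / (n_spectral / 2)``."""
    dk = np.pi / (2.0 * z_range_air_um)
    j = np.arange(n_spectral) - n_spectral // 2
    return k_center + j * dk


def warped_k_grid(n_spectral: int, z_range_air_um: float, warp: float = 0.15,
                  k_center: float = K_CENTER_UM) -> np.ndarray:
    """Quadratically warped (non-uniform, monotone) grid with the same span
    and endpoints as the uniform grid; emulates an uncalibrated spectrometer."""
    if not (0 <= warp < 0.5):
        raise ValueError("warp must be in [0, 0.5) for monotonicity")
    ku = uniform_k_grid(n_spectral, z_range_air_um, k_center)
    half = 0.5 * (ku[-1] - ku[0])
    mid = 0.5 * (ku[-1] + ku[0])
    v = (ku - mid) / half
    return mid + half * (v + warp * (v ** 2 - 1.0))


def dispersion_phase(k: np.ndarray, coeffs: np.ndarray | None) -> np.ndarray:
    """Polynomial dispersion phase ``sum_p c_p * u**(p+2)`` with
    ``u = (k - k_c) / (span / 2)``; ``coeffs`` = (c2, c3, ...)."""
    if coeffs is None or len(coeffs) == 0:
        return np.zeros_like(k)
    half = 0.5 * (k[-1] - k[0])
    mid = 0.5 * (k[-1] + k[0])
    u = (k - mid) / half
    phi = np.zeros_like(k)
    for p, c in enumerate(coeffs):
        phi += c * u ** (p + 2)
    return phi


# ---------------------------------------------------------------------------
# scatterer sampling
# ---------------------------------------------------------------------------

@dataclass
class ScattererSet:
    """Discrete scatterers of one scene, in acquisition (column) order."""

    z_um: np.ndarray        # geometric depth in the scene grid (um)
    amp: np.ndarray
    phase0: np.ndarray
    col: np.ndarray         # flattened column index y * n_x + x
    vessel_index: np.ndarray  # -1 = static, else row into scene.vessel_table
    step_um: np.ndarray     # axial random-walk scale when mobile
    n_cols: int

    @property
    def is_static(self) -> np.ndarray:
        return self.vessel_index < 0


def sample_scatterers(
    scene: Scene,
    seed: int,
    *,
    per_column: int = 24,
    base_amp: float = 0.004,
    surface_amp_factor: float = 3.0,
    vessel_amp_factor: float = 2.5,
) -> ScattererSet:
    """Draw the discrete scatterers realizing a scene.

    Per column: ``per_column`` static tissue scatterers at uniform depths below
    the surface (amplitude proportional to the local reflectivity with a
    Rayleigh speckle factor), one deterministic bright surface scatterer, and
    one scatterer per vessel voxel.
    """
    rng = np.random.default_rng([seed, 7])
    ny, nx, nz = scene.shape
    dz = scene.pitch_um[2]
    n_cols = ny * nx
    surf = scene.surface_depth_um.reshape(-1)
    z_ext = scene.z_extent_um

    # static tissue scatterers
    u = rng.random((n_cols, per_column))
    z_static = surf[:, None] + u * (z_ext - surf[:, None])
    zi = np.minimum((z_static / dz).astype(int), nz - 1)
    refl = scene.tissue_reflectivity.reshape(n_cols, nz)
    a_static = base_amp * refl[np.arange(n_cols)[:, None], zi] * rng.rayleigh(1.0, zi.shape)

    # surface reflection (scaled by the local reflectivity so a void scene
    # stays fringe-free)
    z_surf = surf[:, None]
    zi_surf = np.minimum((surf / dz).astype(int), nz - 1)
    refl_surf = refl[np.arange(n_cols), np.minimum(zi_surf + 1, nz - 1)]
    a_surf = (surface_amp_factor * base_amp * refl_surf)[:, None]

    # vessel scatterers: one per vessel voxel
    vz, vcol, vidx = [], [], []
    vmap = scene.vessel_map.reshape(n_cols, nz)
    id_to_row = {v.vessel_id: i for i, v in enumerate(scene.vessel_table)}
    cc, zz = np.nonzero(vmap)
    for c, z in zip(cc, zz):
        vz.append((z + 0.5) * dz)
        vcol.append(c)
        vidx.append(id_to_row[int(vmap[c, z])])
    vz = np.asarray(vz, float)
    vcol = np.asarray(vcol, int)
    vidx = np.asarray(vidx, int)
    a_ves = vessel_amp_factor * base_amp * np.ones(vz.shape)
    step = np.array([scene.vessel_table[i].speed_um for i in vidx]) if len(vidx) else np.empty(0)

    z_all = np.concatenate([z_static.ravel(), z_surf.ravel(), vz])
    amp = np.concatenate([a_static.ravel(), a_surf.ravel(), a_ves])
    col = np.concatenate([
        np.repeat(np.arange(n_cols), per_column),
        np.arange(n_cols),
        vcol,
    ])
    vessel_index = np.concatenate([
        np.full(n_cols * per_column, -1), np.full(n_cols, -1), vidx,
    ]).astype(int)
    step_all = np.concatenate([np.zeros(n_cols * per_column), np.zeros(n_cols), step])
    phase0 = rng.uniform(0, 2 * np.pi, z_all.shape)
    return ScattererSet(z_um=z_all, amp=amp, phase0=phase0, col=col,
                        vessel_index=vessel_index, step_um=step_all, n_cols=n_cols)


# ---------------------------------------------------------------------------
# spectral series container
# ---------------------------------------------------------------------------

@dataclass
class SpectralSeries:
    """One raw 4-D acquisition: (Y, repeat, X, spectral pixel)."""

    data: np.ndarray
    wavenumber_grid: np.ndarray
    timestamps_s: np.ndarray
    protocol: AcquisitionProtocol
    dispersion_truth: np.ndarray
    frame_index: int = 0

    def validate(self) -> None:
        p = self.protocol
        if self.data.shape != (p.n_y, p.n_repeats, p.n_x, p.n_spectral):
            raise ValueError("data shape does not match protocol")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def envelope(k: np.ndarray) -> np.ndarray:
    """Gaussian source envelope over the sampled span."""
    half = 0.5 * (k[-1] - k[0])
    mid = 0.5 * (k[-1] + k[0])
    return np.exp(-(((k - mid) / (2 * ENVELOPE_WIDTH_FRAC * half)) ** 2))


def noise_std_for_snr(snr_db: float, amp: float, n_spectral: int,
                      env_mean: float = 0.7) -> float:
    """Spectral-noise sigma giving approximately ``snr_db`` amplitude SNR for a
    scatterer of amplitude ``amp`` after an orthonormal FFT."""
    return amp * env_mean * np.sqrt(n_spectral) / 10 ** (snr_db / 20.0)


class OCMSimulator:
    """Synthesize spectral series for a scene, caching the static fringe field.

    The static contribution to every spectrum is identical across repeats and
    frames (up to the bulk phase), so its complex fringe phasor sum is computed
    once; per frame only vessel scatterers, bulk phase and noise are redrawn.
    """

    def __init__(
        self,
        scene: Scene,
        protocol: AcquisitionProtocol,
        *,
        seed: int,
        timecourse: StrokeTimecourse | None = None,
        dispersion_coeffs: np.ndarray | None = None,
        bulk_std_rad: float = 0.0,
        bulk_phases: np.ndarray | None = None,
        noise_std: float = 0.0,
        k_grid: np.ndarray | None = None,
        scatterers: ScattererSet | None = None,
        z_offset_air_um: float = 100.0,
        refractive_index: float | None = None,
        shadow_scramble_rad: float = 0.0,
        sample_kw: dict | None = None,
    ) -> None:
        ny, nx, _ = scene.shape
        if (protocol.n_y, protocol.n_x) != (ny, nx):
            raise ValueError(
                f"protocol lateral grid ({protocol.n_y}, {protocol.n_x}) must match "
                f"scene grid ({ny}, {nx})"
            )
        self.scene = scene
        self.protocol = protocol
        self.seed = int(seed)
        self.timecourse = timecourse
        self.dispersion = np.asarray(dispersion_coeffs, float) if dispersion_coeffs is not None else np.zeros(0)
        self.bulk_std = float(bulk_std_rad)
        self.bulk_phases = bulk_phases
        self.noise_std = float(noise_std)
        self.k = k_grid if k_grid is not None else uniform_k_grid(
            protocol.n_spectral, protocol.z_range_air_mm * 1e3)
        self.z_offset = float(z_offset_air_um)
        self.n_idx = float(refractive_index if refractive_index is not None else scene.refractive_index)
        self.shadow = float(shadow_scramble_rad)
        self.scatterers = scatterers if scatterers is not None else sample_scatterers(
            scene, seed, **(sample_kw or {}))
        self._check_depth_range()
        self.env = envelope(self.k)
        self.phi_disp = dispersion_phase(self.k, self.dispersion)
        self._static_field = None  # (n_cols, n_spectral) complex

    # -- geometry -----------------------------------------------------------

    def z_optical(self, z_um: np.ndarray) -> np.ndarray:
        """Air-equivalent optical depth of a geometric scene depth."""
        return self.z_offset + self.n_idx * np.asarray(z_um)

    def _check_depth_range(self) -> None:
        z_max = self.protocol.z_range_air_mm * 1e3
        zo = self.z_optical(self.scatterers.z_um)
        if zo.size and zo.max() >= z_max:
            raise ValueError(
                f"scatterer optical depth {zo.max():.0f} um beyond unambiguous "
                f"range {z_max:.0f} um (would alias)"
            )

    # -- fringe synthesis ---------------------------------------------------

    def _phasor_sum(self, z_um: np.ndarray, amp: np.ndarray, phase0: np.ndarray,
                    col: np.ndarray, n_rows: int | None = None) -> np.ndarray:
        """Accumulate ``amp * exp(i (2 z_opt k + phase0))`` per column.

        On a uniform wavenumber grid the fringe of one scatterer is a
        geometric sequence along k, so the spectrum is built by recursive
        multiplication instead of a full complex exponential per sample.
        """
        n_k = self.k.size
        if n_rows is None:
            n_rows = self.scatterers.n_cols
        out = np.zeros((n_rows, n_k), np.complex128)
        if z_um.size == 0:
            return out
        order = np.argsort(col, kind="stable")
        z_um, amp, phase0, col = z_um[order], amp[order], phase0[order], col[order]
        dk = np.diff(self.k)
        uniform = np.allclose(dk, dk[0], rtol=1e-8, atol=0.0)
        chunk = max(1, min(z_um.size, int(48e6 / n_k)))
        for a in range(0, z_um.size, chunk):
            b = min(a + chunk, z_um.size)
            zo = 2.0 * self.z_optical(z_um[a:b])
            uniq, starts = np.unique(col[a:b], return_index=True)
            if uniform:
                # geometric recursion along k in single precision, laid out
                # k-major so every step is a contiguous multiply; the relative
                # error after n_k steps stays ~1e-5, far below the speckle and
                # noise scales of interest
                ph = np.empty((n_k, b - a), np.complex64)
                ph[0] = (amp[a:b] * np.exp(1j * (zo * self.k[0] + phase0[a:b]))
                         ).astype(np.complex64)
                step = np.exp(1j * zo * dk[0]).astype(np.complex64)
                for j in range(1, n_k):
                    np.multiply(ph[j - 1], step, out=ph[j])
                out[uniq] += np.add.reduceat(ph, starts, axis=1).T
            else:
                ph = amp[a:b, None] * np.exp(
                    1j * (zo[:, None] * self.k[None, :] + phase0[a:b, None]))
                out[uniq] += np.add.reduceat(ph, starts, axis=0)
        return out

    def static_field(self) -> np.ndarray:
        if self._static_field is None:
            s = self.scatterers
            sel = s.is_static
            self._static_field = self._phasor_sum(s.z_um[sel], s.amp[sel],
                                                  s.phase0[sel], s.col[sel])
        return self._static_field

    def frame(self, frame_index: int = 0) -> SpectralSeries:
        """Synthesize one volumetric acquisition."""
        p = self.protocol
        s = self.scatterers
        rng = np.random.default_rng([self.seed, 1009, int(frame_index)])
        n_cols = s.n_cols

        # perfusion factors for this frame
        vsel = ~s.is_static
        n_ves = int(vsel.sum())
        if self.timecourse is not None:
            stage = self.timecourse.stage_of(frame_index)
            pf = self.timecourse.perfusion[stage][s.vessel_index[vsel]]
        else:
            pf = np.ones(n_ves)
        mobile = rng.random(n_ves) < pf

        # per-repeat vessel positions: axial random walk for mobile scatterers
        steps = rng.normal(0.0, 1.0, (p.n_repeats - 1, n_ves)) if p.n_repeats > 1 else np.zeros((0, n_ves))
        steps *= (s.step_um[vsel] * mobile)[None, :]
        walks = np.concatenate([np.zeros((1, n_ves)), np.cumsum(steps, axis=0)], axis=0)

        # bulk phases per (y, repeat)
        if self.bulk_phases is not None:
            bp = np.asarray(self.bulk_phases, float)
            if bp.ndim == 1:
                bp = np.broadcast_to(bp, (p.n_y, p.n_repeats))
        elif self.bulk_std > 0:
            bp = rng.normal(0.0, self.bulk_std, (p.n_y, p.n_repeats))
            bp[:, 0] = 0.0
        else:
            bp = np.zeros((p.n_y, p.n_repeats))

        # optional trans-vessel phase scrambling of the shadow below flowing
        # vessels: static scatterers deeper than a mobile vessel scatterer in
        # the same column acquire extra per-repeat phase jitter
        shadow_jitter = None
        if self.shadow > 0 and n_ves:
            vcols = s.col[vsel][mobile]
            vdepth = s.z_um[vsel][mobile]
            min_vdepth = np.full(n_cols, np.inf)
            np.minimum.at(min_vdepth, vcols, vdepth)
            st = s.is_static
            below = s.z_um[st] > min_vdepth[s.col[st]]
            shadow_jitter = (below, st)

        P_static = self.static_field()
        out = np.empty((p.n_y, p.n_repeats, p.n_x, p.n_spectral), np.float32)
        phase_common = self.phi_disp
        zv0 = s.z_um[vsel]
        if n_ves:
            # all repeats in one accumulation pass (rows = repeat-major columns)
            R = p.n_repeats
            z_all = (zv0[None, :] + walks).ravel()
            col_all = (s.col[vsel][None, :] + np.arange(R)[:, None] * n_cols).ravel()
            Pv_all = self._phasor_sum(
                z_all, np.tile(s.amp[vsel], R), np.tile(s.phase0[vsel], R),
                col_all, n_rows=R * n_cols).reshape(R, n_cols, p.n_spectral)
        else:
            Pv_all = None
        for r in range(p.n_repeats):
            Pv = Pv_all[r] if Pv_all is not None else 0.0
            if shadow_jitter is not None and r > 0:
                below, st = shadow_jitter
                jit = np.zeros(int(st.sum()))
                jit[below] = rng.normal(0.0, self.shadow, int(below.sum()))
                Pj = self._phasor_sum(s.z_um[st][below], s.amp[st][below],
                                      s.phase0[st][below] + jit[below], s.col[st][below])
                Pj0 = self._phasor_sum(s.z_um[st][below], s.amp[st][below],
                                       s.phase0[st][below], s.col[st][below])
                P = P_static - Pj0 + Pj + Pv
            else:
                P = P_static + Pv
            # Re{P * exp(i(phi_disp + psi))} in real arithmetic
            phi = phase_common[None, :] + bp[:, r][:, None]  # (n_y, n_k)
            c, sn = np.cos(phi), np.sin(phi)
            P3 = P.reshape(p.n_y, p.n_x, p.n_spectral)
            fr = 2.0 * (P3.real * c[:, None, :] - P3.imag * sn[:, None, :])
            fr += DC_LEVEL
            fr *= self.env[None, None, :]
            out[:, r] = fr

        if self.noise_std > 0:
            out += rng.normal(0.0, self.noise_std, out.shape).astype(np.float32)

        t0 = frame_index * (protocol_timing(p).total_scan_s + 8.3)  # dead time to next frame
        series = SpectralSeries(
            data=out,
            wavenumber_grid=self.k.copy(),
            timestamps_s=t0 + protocol_timing(p).timestamps_s,
            protocol=p,
            dispersion_truth=self.dispersion.copy(),
            frame_index=frame_index,
        )
        series.validate()
        return series

    def frames(self):
        """Iterate over the whole time course (requires a timecourse)."""
        if self.timecourse is None:
            raise ValueError("no timecourse attached")
        for i in range(self.timecourse.n_frames):
            yield self.frame(i)


def simulate_spectra(
    scene: Scene,
    protocol: AcquisitionProtocol,
    *,
    seed: int,
    timecourse: StrokeTimecourse | None = None,
    frame_index: int = 0,
    **kwargs,
) -> SpectralSeries:
    """One-shot synthesis of a single volumetric acquisition (see
    :class:`OCMSimulator` for the keyword surface)."""
    sim = OCMSimulator(scene, protocol, seed=seed, timecourse=timecourse, **kwargs)
    return sim.frame(frame_index)
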