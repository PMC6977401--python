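"""Ground-truth vascular phantoms.

A :class:`Scene` is a voxelized patch of cortex under a cranial window: a
static tissue scattering field, a labelled vessel map (pial vessels, penetrating
arterioles, capillaries at three depth bands below the brain surface), an
en face mask of the large superficial vessels, and the per-column depth of the
tissue surface.  A :class:`StrokeTimecourse` assigns each vessel a perfusion
factor per experimental stage (baseline / dye / occlusion / recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: axial displacement scale (um per repeat interval) by vessel flow class;
#: all classes fully decorrelate the phasor at the source wavenumber, the
#: class distinction matters only when sub-decorrelation displacements are
#: requested explicitly.
FLOW_CLASS_SPEED_UM = {"pial": 2.0, "arteriole": 1.0, "capillary": 0.5}


@dataclass(frozen=True)
class Vessel:
    """One vessel segment: a cylinder along a grid axis.

    ``depth_um`` is the centreline depth below the brain surface.  For the
    vertical (``axis='z'``) penetrating vessels ``depth_um`` and ``depth2_um``
    bound the spanned depth interval.
    """

    vessel_id: int
    axis: str  # 'x', 'y' (horizontal) or 'z' (penetrating)
    radius_um: float
    depth_um: float
    flow_class: str = "capillary"
    y_um: float | None = None  # centreline lateral position(s)
    x_um: float | None = None
    depth2_um: float | None = None  # only for axis='z'
    band: int | None = None  # declared depth band (1-based), validated at build

    @property
    def speed_um(self) -> float:
        return FLOW_CLASS_SPEED_UM[self.flow_class]


@dataclass
class Scene:
    """Voxelized ground-truth phantom on a (Y, X, Z) grid."""

    shape: tuple[int, int, int]  # (n_y, n_x, n_z)
    pitch_um: tuple[float, float, float]  # (dy, dx, dz)
    tissue_reflectivity: np.ndarray  # (Y, X, Z), field-amplitude units, >= 0
    vessel_map: np.ndarray  # (Y, X, Z) int16, 0 = tissue
    vessel_table: list[Vessel]
    large_vessel_mask: np.ndarray  # (Y, X) bool
    surface_depth_um: np.ndarray  # (Y, X), tissue surface depth from grid top
    refractive_index: float = 1.35

    def validate(self) -> None:
        ny, nx, nz = self.shape
        if self.tissue_reflectivity.shape != (ny, nx, nz):
            raise ValueError("reflectivity shape does not match grid")
        if np.any(self.tissue_reflectivity < 0):
            raise ValueError("reflectivity must be non-negative")
        z_ext = nz * self.pitch_um[2]
        if np.any(self.surface_depth_um < 0) or np.any(self.surface_depth_um >= z_ext):
            raise ValueError("surface depth outside [0, z extent)")

    @property
    def z_extent_um(self) -> float:
        return self.shape[2] * self.pitch_um[2]

    def depth_below_surface_um(self) -> np.ndarray:
        """(Y, X, Z) depth of each voxel centre below the local surface (um)."""
        z = (np.arange(self.shape[2]) + 0.5) * self.pitch_um[2]
        return z[None, None, :] - self.surface_depth_um[:, :, None]

    def vessel_columns(self) -> np.ndarray:
        """(Y, X) bool: columns containing any vessel voxel."""
        return (self.vessel_map > 0).any(axis=2)


def _cylinder_coverage(du: np.ndarray, dv: np.ndarray, radius: float,
                       pu: float, pv: float, sub: int = 11) -> np.ndarray:
    """Fraction of each (u, v) voxel cross-section covered by a disc of
    ``radius`` centred at the origin, estimated by sub-sampling."""
    off = (np.arange(sub) + 0.5) / sub - 0.5
    uu = du[..., None, None] + off[None, :, None] * pu
    vv = dv[..., None, None] + off[None, None, :] * pv
    inside = (uu ** 2 + vv ** 2) <= radius ** 2
    return inside.mean(axis=(-2, -1))


def _rasterize_disc(cov: np.ndarray) -> np.ndarray:
    """Area-preserving boolean rasterization of a coverage field: keep the
    ``round(total coverage)`` best-covered voxels (at least one), so voxel
    counts track the analytic cross-section area even for sub-voxel radii."""
    k = max(1, int(round(float(cov.sum()))))
    flat = np.argsort(cov, axis=None)[::-1][:k]
    sel = np.zeros(cov.size, bool)
    sel[flat] = True
    return sel.reshape(cov.shape)


def build_scene(
    shape: tuple[int, int, int],
    pitch_um: tuple[float, float, float],
    vessels: list[Vessel],
    seed: int,
    *,
    surface_depth_um: float | np.ndarray = 25.0,
    surface_tilt_um_per_px: tuple[float, float] = (0.0, 0.0),
    tissue_reflectivity: float = 1.0,
    large_vessel_radius_um: float = 15.0,
    refractive_index: float = 1.35,
) -> Scene:
    """Rasterize a vessel architecture into a ground-truth scene.

    Cylinders are rasterized area-preservingly: per cross-section the voxels
    best covered by the disc are kept, as many as the disc's area spans in
    voxel units (at least one), so voxel counts track analytic cylinder
    volumes and capillaries thinner than the grid pitch still form connected
    centrelines.  Deterministic given ``seed`` (the seed reserves room for
    stochastic reflectivity texture; the default texture is uniform).
    """
    ny, nx, nz = shape
    if min(shape) < 1:
        raise ValueError("zero-size grid")
    dy, dx, dz = pitch_um
    z_ext = nz * dz

    surf = np.broadcast_to(np.asarray(surface_depth_um, float), (ny, nx)).copy()
    ty, tx = surface_tilt_um_per_px
    if ty or tx:
        surf = surf + ty * np.arange(ny)[:, None] + tx * np.arange(nx)[None, :]

    refl = np.zeros(shape, np.float32)
    zc = (np.arange(nz) + 0.5) * dz
    in_tissue = zc[None, None, :] >= surf[:, :, None]
    refl[in_tissue] = tissue_reflectivity

    vmap = np.zeros(shape, np.int16)
    mean_surf = float(surf.mean())
    for v in vessels:
        if 2 * v.radius_um > min(ny * dy, z_ext):
            raise ValueError(f"vessel {v.vessel_id}: radius {v.radius_um} um exceeds grid")
        if v.axis in ("x", "y"):
            zc_center = mean_surf + v.depth_um
            if not (0 <= zc_center < z_ext):
                raise ValueError(f"vessel {v.vessel_id}: centreline depth outside grid")
            # lateral axis perpendicular to the cylinder
            if v.axis == "x":
                lat = (np.arange(ny) + 0.5) * dy - (v.y_um if v.y_um is not None else ny * dy / 2)
                platch = dy
            else:
                lat = (np.arange(nx) + 0.5) * dx - (v.x_um if v.x_um is not None else nx * dx / 2)
                platch = dx
            dzv = zc - zc_center
            cov = _cylinder_coverage(lat[:, None], dzv[None, :], v.radius_um, platch, dz)
            li, zi = np.nonzero(_rasterize_disc(cov))
            if v.axis == "x":
                vmap[li, :, zi] = v.vessel_id  # all x, paired (y, z)
            else:
                vmap[:, li, zi] = v.vessel_id  # all y, paired (x, z)
        elif v.axis == "z":
            x0 = v.x_um if v.x_um is not None else nx * dx / 2
            y0 = v.y_um if v.y_um is not None else ny * dy / 2
            yy = (np.arange(ny) + 0.5) * dy - y0
            xx = (np.arange(nx) + 0.5) * dx - x0
            cov = _cylinder_coverage(yy[:, None], xx[None, :], v.radius_um, dy, dx)
            sel = _rasterize_disc(cov)
            d2 = v.depth2_um if v.depth2_um is not None else v.depth_um
            z0, z1 = mean_surf + v.depth_um, mean_surf + d2
            if not (0 <= z0 < z_ext):
                raise ValueError(f"vessel {v.vessel_id}: depth outside grid")
            zin = (zc >= z0) & (zc < min(z1, z_ext))
            yi, xi = np.nonzero(sel)
            zi = np.nonzero(zin)[0]
            vmap[yi[:, None], xi[:, None], zi[None, :]] = v.vessel_id
        else:
            raise ValueError(f"vessel {v.vessel_id}: unknown axis {v.axis!r}")

    large = np.zeros((ny, nx), bool)
    for v in vessels:
        if v.radius_um >= large_vessel_radius_um:
            large |= (vmap == v.vessel_id).any(axis=2)

    scene = Scene(
        shape=shape,
        pitch_um=pitch_um,
        tissue_reflectivity=refl,
        vessel_map=vmap,
        vessel_table=list(vessels),
        large_vessel_mask=large,
        surface_depth_um=surf,
        refractive_index=refractive_index,
    )
    scene.validate()
    _check_band_membership(scene)
    return scene


def _check_band_membership(scene: Scene, edges_um: tuple[float, ...] = (0.0, 160.0, 320.0)) -> None:
    """Verify each vessel's voxels fall in its declared depth band."""
    depth = scene.depth_below_surface_um()
    hi = scene.z_extent_um
    for v in scene.vessel_table:
        if v.band is None:
            continue
        sel = scene.vessel_map == v.vessel_id
        if not sel.any():
            continue
        d = depth[sel]
        lo = edges_um[v.band - 1]
        up = edges_um[v.band] if v.band < len(edges_um) else hi
        # allow half a voxel of rasterization slack at band edges
        slack = scene.pitch_um[2]
        if d.min() < lo - v.radius_um - slack or d.max() >= up + v.radius_um + slack:
            raise ValueError(
                f"vessel {v.vessel_id} voxels at depths [{d.min():.0f}, {d.max():.0f}] um "
                f"inconsistent with declared band {v.band}"
            )


# ---------------------------------------------------------------------------
# stroke time course
# ---------------------------------------------------------------------------

STAGE_ORDER = ("baseline", "dye", "occlusion", "recovery")


@dataclass
class StrokeTimecourse:
    """Stage structure of a photothrombotic stroke experiment.

    ``stage_bounds`` maps stage name to a half-open frame interval; stages are
    contiguous, ordered baseline -> dye -> occlusion -> recovery (a stage may
    be empty).  ``perfusion`` maps stage name to a per-vessel factor in [0, 1]:
    the fraction of that vessel's scatterers that remain mobile.
    """

    stage_bounds: dict[str, tuple[int, int]]
    perfusion: dict[str, np.ndarray]
    occluded_region: np.ndarray | None = None  # (Y, X) bool

    def __post_init__(self) -> None:
        prev_end = None
        for name in STAGE_ORDER:
            if name not in self.stage_bounds:
                raise ValueError(f"missing stage {name!r}")
            a, b = self.stage_bounds[name]
            if b < a:
                raise ValueError(f"stage {name!r} has negative length")
            if prev_end is not None and a != prev_end:
                raise ValueError("stages must be contiguous and ordered")
            prev_end = b
        for name, f in self.perfusion.items():
            f = np.asarray(f, float)
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError(f"perfusion factors for {name!r} outside [0, 1]")
            self.perfusion[name] = f
        if not np.all(self.perfusion["baseline"] == 1.0):
            raise ValueError("baseline perfusion factors must all be 1")

    @property
    def n_frames(self) -> int:
        return self.stage_bounds[STAGE_ORDER[-1]][1]

    def stage_of(self, frame: int) -> str:
        for name in STAGE_ORDER:
            a, b = self.stage_bounds[name]
            if a <= frame < b:
                return name
        raise IndexError(f"frame {frame} outside time course (0..{self.n_frames - 1})")

    def frames(self, stage: str) -> list[int]:
        a, b = self.stage_bounds[stage]
        return list(range(a, b))


def make_timecourse(
    scene: Scene,
    *,
    n_baseline: int,
    n_occlusion: int,
    n_recovery: int = 0,
    n_dye: int = 0,
    occlusion_factor_by_band: dict[int, float] | float = 0.1,
    recovery_factor_by_band: dict[int, float] | float = 1.0,
    band_edges_um: tuple[float, ...] = (0.0, 160.0, 320.0),
    occluded_region: np.ndarray | None = None,
    spared_vessels: tuple[int, ...] = (),
) -> StrokeTimecourse:
    """Build a stage-wise time course from per-band perfusion factors.

    Vessels listed in ``spared_vessels`` keep baseline perfusion throughout
    (the paper's untouched vein running alongside the occluded artery).
    """
    n_v = len(scene.vessel_table)

    def band_of(v: Vessel) -> int:
        if v.band is not None:
            return v.band
        d = v.depth_um
        b = int(np.searchsorted(band_edges_um, d, side="right"))
        return max(b, 1)

    def factors(spec_: dict[int, float] | float) -> np.ndarray:
        out = np.ones(n_v)
        for i, v in enumerate(scene.vessel_table):
            if v.vessel_id in spared_vessels:
                continue
            out[i] = spec_ if np.isscalar(spec_) else spec_.get(band_of(v), 1.0)
        return out

    b0 = n_baseline
    b1 = b0 + n_dye
    b2 = b1 + n_occlusion
    b3 = b2 + n_recovery
    return StrokeTimecourse(
        stage_bounds={
            "baseline": (0, b0),
            "dye": (b0, b1),
            "occlusion": (b1, b2),
            "recovery": (b2, b3),
        },
        perfusion={
            "baseline": np.ones(n_v),
            "dye": np.ones(n_v),
            "occlusion": factors(occlusion_factor_by_band),
            "recovery": factors(recovery_factor_by_band),
        },
        occluded_region=occluded_region,
    )


# ---------------------------------------------------------------------------
# canonical study scene
# ---------------------------------------------------------------------------

def default_stroke_scene(
    seed: int,
    *,
    shape: tuple[int, int, int] = (64, 64, 256),
    pitch_um: tuple[float, float, float] = (17.2, 17.2, 2.5),
) -> Scene:
    """The canonical desk-scale cortical phantom used by the study analyses.

    Two large pial vessels (one artery, one vein) plus small pial branches in
    the meningeal band, penetrating arterioles in the 160-320 um band, and a
    capillary bed below 320 um.
    """
    rng = np.random.default_rng([seed, 11])
    ny, nx, nz = shape
    dy, dx, _ = pitch_um
    wy, wx = ny * dy, nx * dx
    vessels: list[Vessel] = []
    vid = 1
    # large pial artery + vein, horizontal along x
    for y_frac, depth in ((0.30, 60.0), (0.62, 90.0)):
        vessels.append(Vessel(vid, "x", radius_um=25.0, depth_um=depth,
                              flow_class="pial", y_um=y_frac * wy, band=1))
        vid += 1
    # small pial vessels
    for _ in range(6):
        vessels.append(Vessel(vid, "x", radius_um=8.0,
                              depth_um=float(rng.uniform(30, 140)),
                              flow_class="pial", y_um=float(rng.uniform(0.05, 0.95) * wy),
                              band=1))
        vid += 1
    # penetrating arterioles, vertical
    for _ in range(8):
        vessels.append(Vessel(vid, "z", radius_um=6.0, depth_um=165.0, depth2_um=318.0,
                              flow_class="arteriole",
                              x_um=float(rng.uniform(0.1, 0.9) * wx),
                              y_um=float(rng.uniform(0.1, 0.9) * wy), band=2))
        vid += 1
    # capillary bed
    for _ in range(20):
        axis = "x" if rng.random() < 0.5 else "y"
        kw = {"y_um": float(rng.uniform(0.05, 0.95) * wy)} if axis == "x" else \
             {"x_um": float(rng.uniform(0.05, 0.95) * wx)}
        vessels.append(Vessel(vid, axis, radius_um=3.0,
                              depth_um=float(rng.uniform(330, 600)),
                              flow_class="capillary", band=3, **kw))
        vid += 1
    return build_scene(shape, pitch_um, vessels, seed)
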