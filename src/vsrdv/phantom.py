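"""Synthetic pulsatile neurovascular flow phantom with ground-truth velocities.

The phantom emulates a silicone circle-of-Willis replica suspended in agar:
cylindrical vessels with Poiseuille (parabolic) through-plane flow, a shared
pulsatile waveform, static background tissue for phase-offset correction, and
analytic cross-sectional measurement planes.  Vessel peak speeds are chosen
to straddle the low venc so that both aliased and non-aliased voxels exist.

Units: mm for geometry, cm/s for velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StraightCenterline",
    "ArcCenterline",
    "VesselSpec",
    "PlaneSpec",
    "PhantomConfig",
    "FlowPhantom",
    "make_phantom",
    "truth_aliasing_mask",
    "analytic_plane_stats",
    "default_config",
    "raised_cosine_waveform",
]


def raised_cosine_waveform(phase: np.ndarray, systole_fraction: float = 0.3,
                           baseline: float = 0.2) -> np.ndarray:
    """Raised-cosine systolic pulse on a diastolic baseline.

    A systolic bump occupies the first ``systole_fraction`` of the cycle;
    the rest of the cycle sits at ``baseline`` (fraction of peak).
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    w = np.full_like(phase, baseline)
    sys = phase < systole_fraction
    w[sys] = baseline + (1.0 - baseline) * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * phase[sys] / systole_fraction)
    )
    return w


@dataclass(frozen=True)
class StraightCenterline:
    start: tuple[float, float, float]
    end: tuple[float, float, float]

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        p0 = np.asarray(self.start, float)
        p1 = np.asarray(self.end, float)
        length = float(np.linalg.norm(p1 - p0))
        n = max(int(np.ceil(length / spacing)) + 1, 2)
        ts = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        tan = np.tile((p1 - p0) / length, (n, 1))
        return pts, tan


@dataclass(frozen=True)
class ArcCenterline:
    """Circular arc (U-bend): center + R*(cos(a)*u + sin(a)*v), a in [a0, a1]."""

    center: tuple[float, float, float]
    bend_radius: float
    axis_u: tuple[float, float, float]
    axis_v: tuple[float, float, float]
    angle_range: tuple[float, float] = (-np.pi / 2, np.pi / 2)

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        a0, a1 = self.angle_range
        arc_len = abs(a1 - a0) * self.bend_radius
        n = max(int(np.ceil(arc_len / spacing)) + 1, 2)
        ang = np.linspace(a0, a1, n)
        pts = c[None, :] + self.bend_radius * (
            np.cos(ang)[:, None] * u[None, :] + np.sin(ang)[:, None] * v[None, :]
        )
        tan = -np.sin(ang)[:, None] * u[None, :] + np.cos(ang)[:, None] * v[None, :]
        tan *= np.sign(a1 - a0)
        return pts, tan


@dataclass(frozen=True)
class VesselSpec:
    """One vessel: a centerline swept by a circular lumen with Poiseuille flow."""

    name: str
    centerline: StraightCenterline | ArcCenterline
    radius_mm: float
    peak_centerline_speed: float  # cm/s
    connected_to: tuple[str, ...] = ()

    def __post_init__(self):
        if self.peak_centerline_speed <= 0:
            raise ValueError(f"{self.name}: peak speed must be positive")


@dataclass(frozen=True)
class PlaneSpec:
    """Analysis plane: origin + unit normal, square extent, owning vessel."""

    origin: tuple[float, float, float]
    normal: tuple[float, float, float]
    extent_mm: float
    vessel_name: str

    def __post_init__(self):
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("plane normal must have unit norm")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: float = 0.8
    n_frames: int = 10
    vessels: list[VesselSpec] = field(default_factory=list)
    planes: list[PlaneSpec] = field(default_factory=list)
    magnitude_lumen: float = 1.0
    magnitude_static: float = 0.6
    magnitude_outside: float = 0.02
    texture_sd: float = 0.02        # seeded static-tissue speckle
    # outer rim treated as "outside" (air).  Default 0: the imaging volume
    # sits entirely inside the agar block, as in the physical setup — a
    # sharp tissue/air box edge would ring through the whole volume.
    margin_voxels: int = 0
    systole_fraction: float = 0.3
    diastolic_baseline: float = 0.2


@dataclass
class FlowPhantom:
    """Ground truth: velocity (3, nx, ny, nz, nt) cm/s, magnitude, masks."""

    config: PhantomConfig
    velocity: np.ndarray        # float32 (3, nx, ny, nz, nt)
    magnitude: np.ndarray       # float32 (nx, ny, nz, nt)
    static_mask: np.ndarray     # bool (nx, ny, nz)
    lumen_mask: np.ndarray      # bool (nx, ny, nz)
    waveform: np.ndarray        # (nt,), normalized so max over frames == 1
    seed: int = 0

    @property
    def vessels(self) -> list[VesselSpec]:
        return self.config.vessels

    @property
    def planes(self) -> list[PlaneSpec]:
        return self.config.planes

    @property
    def voxel_size_mm(self) -> float:
        return self.config.voxel_size_mm

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.config.voxel_size_mm
        nx, ny, nz = self.config.shape
        return (np.arange(nx) * h, np.arange(ny) * h, np.arange(nz) * h)


def _min_radius_voxels(cfg: PhantomConfig) -> float:
    return 2.0 * cfg.voxel_size_mm


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> FlowPhantom:
    """Voxelize the vessel set onto the grid; deterministic for a fixed seed.

    Poiseuille profile v(r) = v_max(t) * (1 - (r/Rad)^2) along the local
    centerline tangent, with partial-volume weighting of the magnitude at
    the lumen edge.  Raises if two unconnected vessels claim the same voxel
    with inconsistent velocities.
    """
    cfg = config if config is not None else default_config()
    if not cfg.vessels:
        raise ValueError("phantom needs at least one vessel")
    h = cfg.voxel_size_mm
    nx, ny, nz = cfg.shape
    nt = cfg.n_frames

    for ves in cfg.vessels:
        if ves.radius_mm < _min_radius_voxels(cfg):
            raise ValueError(f"{ves.name}: radius must span >= 2 voxels")

    phases = np.arange(nt) / nt
    wave = raised_cosine_waveform(phases, cfg.systole_fraction, cfg.diastolic_baseline)
    wave = wave / wave.max()  # peak over the sampled frames is exactly 1

    xs = np.arange(nx) * h
    ys = np.arange(ny) * h
    zs = np.arange(nz) * h
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    n_vox = coords.shape[0]
    best_ratio = np.full(n_vox, np.inf)
    owner = np.full(n_vox, -1, dtype=np.int32)
    speed_map = np.zeros(n_vox, dtype=np.float32)      # peak speed * profile
    dir_map = np.zeros((n_vox, 3), dtype=np.float32)
    occ_map = np.zeros(n_vox, dtype=np.float32)
    near_any = np.zeros(n_vox, dtype=bool)

    connected = {v.name: set(v.connected_to) for v in cfg.vessels}
    for v in cfg.vessels:
        for other in v.connected_to:
            connected.setdefault(other, set()).add(v.name)

    for vi, ves in enumerate(cfg.vessels):
        pts, tans = ves.centerline.sample(spacing=0.3 * h)
        tree = cKDTree(pts)
        d, idx = tree.query(coords, workers=-1)
        rad = ves.radius_mm
        # static tissue stops 2 voxels short of the wall: voxels closer are
        # partial-volume / boundary-contaminated, not clean agar
        near = d < rad + 2.0 * h
        near_any |= near
        ratio = d / rad
        occ = np.clip((rad - d) / h + 0.5, 0.0, 1.0)
        profile = np.clip(1.0 - ratio**2, 0.0, None)
        vel_dir = tans[idx]

        # conflict: two unconnected vessels both own a voxel at >=50% occupancy
        clash = (occ >= 0.5) & (occ_map >= 0.5) & (owner >= 0)
        if np.any(clash):
            prev = set(np.unique(owner[clash]))
            for p in prev:
                pname = cfg.vessels[p].name
                if pname not in connected.get(ves.name, set()):
                    sel = clash & (owner == p)
                    dv = (
                        vel_dir[sel] * (ves.peak_centerline_speed * profile[sel])[:, None]
                        - dir_map[sel] * speed_map[sel][:, None]
                    )
                    scale = max(ves.peak_centerline_speed,
                                cfg.vessels[p].peak_centerline_speed)
                    if np.max(np.linalg.norm(dv, axis=1)) > 0.1 * scale:
                        raise ValueError(
                            f"vessels {pname!r} and {ves.name!r} overlap with "
                            "inconsistent velocities"
                        )

        take = near & (ratio < best_ratio)
        best_ratio[take] = ratio[take]
        owner[take] = vi
        speed_map[take] = ves.peak_centerline_speed * profile[take]
        dir_map[take] = vel_dir[take]
        occ_map[take] = occ[take]

    lumen = (occ_map >= 0.5).reshape(nx, ny, nz)

    m = cfg.margin_voxels
    inner = np.zeros((nx, ny, nz), dtype=bool)
    inner[m : nx - m, m : ny - m, m : nz - m] = True
    static = inner & ~near_any.reshape(nx, ny, nz)

    rng = np.random.default_rng(seed)
    texture = rng.normal(0.0, cfg.texture_sd, size=(nx, ny, nz)).astype(np.float32)
    mag3 = np.where(inner, cfg.magnitude_static + texture, cfg.magnitude_outside)
    mag3 = mag3 * (1.0 - occ_map.reshape(nx, ny, nz)) + cfg.magnitude_lumen * occ_map.reshape(nx, ny, nz)
    mag3 = np.clip(mag3, 0.01, None).astype(np.float32)
    magnitude = np.repeat(mag3[..., None], nt, axis=-1)

    vel_static = (dir_map * speed_map[:, None]).T.reshape(3, nx, ny, nz)
    velocity = (vel_static[..., None] * wave[None, None, None, None, :]).astype(np.float32)
    velocity[:, static] = 0.0

    return FlowPhantom(
        config=cfg,
        velocity=velocity,
        magnitude=magnitude,
        static_mask=static,
        lumen_mask=lumen,
        waveform=wave,
        seed=seed,
    )


def truth_aliasing_mask(phantom: FlowPhantom, venc: float) -> np.ndarray:
    """Ground-truth aliasing: |velocity component| > venc, per direction/frame."""
    if venc <= 0:
        raise ValueError("venc must be positive")
    return np.abs(phantom.velocity) > venc


def _plane_vessels(phantom: FlowPhantom, plane: PlaneSpec) -> list[VesselSpec]:
    """Vessels whose centerline crosses the plane disk (slab test)."""
    origin = np.asarray(plane.origin, float)
    normal = np.asarray(plane.normal, float)
    hit = []
    for ves in phantom.vessels:
        pts, _ = ves.centerline.sample(spacing=0.2 * phantom.voxel_size_mm)
        rel = pts - origin[None, :]
        axial = rel @ normal
        inplane = np.linalg.norm(rel - axial[:, None] * normal[None, :], axis=1)
        if np.any((np.abs(axial) < ves.radius_mm) & (inplane < plane.extent_mm / 2)):
            hit.append(ves)
    return hit


def analytic_plane_stats(phantom: FlowPhantom, plane: PlaneSpec):
    """Exact plane statistics from the analytic Poiseuille profile.

    mean = v_max(t)/2, peak = v_max(t), area = pi * Rad^2.  Raises if the
    plane intersects more than one vessel (junction planes are excluded from
    quantification).
    """
    from .hemodynamics import PlaneStats

    hit = _plane_vessels(phantom, plane)
    if len(hit) == 0:
        raise ValueError("plane does not intersect any vessel")
    if len(hit) > 1:
        raise ValueError(
            "plane crosses a junction between vessels: "
            + ", ".join(v.name for v in hit)
        )
    ves = hit[0]
    vmax = ves.peak_centerline_speed * phantom.waveform
    return PlaneStats(
        plane=plane,
        mean_velocity=vmax / 2.0,
        peak_velocity=vmax.copy(),
        area_mm2=float(np.pi * ves.radius_mm**2),
        mean_ta=float(np.mean(vmax / 2.0)),
        peak_ta=float(np.mean(vmax)),
    )


def default_config(shape: tuple[int, int, int] = (64, 64, 32),
                   voxel_size_mm: float = 0.8,
                   n_frames: int = 10) -> PhantomConfig:
    """Desk-scale neurovascular-like phantom.

    Six vessel trees inside a 51x51x26 mm agar block: basilar-like and
    carotid-like straight/curved tubes with systolic peaks of 100, 90 and
    70 cm/s (aliased at venc_low = 55), middle-cerebral-like tubes at 45 and
    40 cm/s (never aliased), and an anterior bifurcation whose daughter
    speeds conserve flow with the parent.  Straight centerlines pass through
    voxel-center rows so the configured peak speed is attained exactly.
    """
    h = voxel_size_mm
    nx, ny, nz = shape
    xmax, ymax, zmax = (nx - 1) * h, (ny - 1) * h, (nz - 1) * h
    zlo, zhi = 2.5 * h, zmax - 2.5 * h

    def vox(i):  # voxel-center coordinate
        return i * h

    vessels = [
        VesselSpec("BA", StraightCenterline((vox(20), vox(15), zlo),
                                            (vox(20), vox(15), zhi)),
                   radius_mm=3.2, peak_centerline_speed=100.0),
        VesselSpec("LICA", StraightCenterline((vox(46), vox(15), zlo),
                                              (vox(46), vox(15), zhi)),
                   radius_mm=2.8, peak_centerline_speed=70.0),
        VesselSpec("RICA", ArcCenterline(center=(vox(33), vox(48), vox(15)),
                                         bend_radius=7.0,
                                         axis_u=(0.0, 0.0, 1.0),
                                         axis_v=(1.0, 0.0, 0.0)),
                   radius_mm=3.2, peak_centerline_speed=90.0),
        VesselSpec("RMCA", StraightCenterline((vox(58), 2.5 * h, vox(8)),
                                              (vox(58), ymax - 2.5 * h, vox(8))),
                   radius_mm=2.0, peak_centerline_speed=45.0),
        VesselSpec("LMCA", StraightCenterline((2.5 * h, vox(32), vox(24)),
                                              (xmax - 2.5 * h, vox(32), vox(24))),
                   radius_mm=2.0, peak_centerline_speed=40.0),
    ]

    # anterior bifurcation: parent flow = sum of daughter flows (Poiseuille)
    apex = (vox(10), vox(56), vox(16))
    r_par, v_par, r_dau = 2.4, 60.0, 1.8
    v_dau = v_par * r_par**2 / (2.0 * r_dau**2)
    c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
    dau_len = 8.0
    vessels += [
        VesselSpec("ACA", StraightCenterline((vox(10), vox(56), zlo), apex),
                   radius_mm=r_par, peak_centerline_speed=v_par,
                   connected_to=("RACA", "LACA")),
        VesselSpec("RACA", StraightCenterline(
            apex, (apex[0] + s * dau_len, apex[1], apex[2] + c * dau_len)),
            radius_mm=r_dau, peak_centerline_speed=v_dau, connected_to=("ACA", "LACA")),
        VesselSpec("LACA", StraightCenterline(
            apex, (apex[0] - s * dau_len, apex[1], apex[2] + c * dau_len)),
            radius_mm=r_dau, peak_centerline_speed=v_dau, connected_to=("ACA", "RACA")),
    ]

    planes = []
    branch = ("ACA", "RACA", "LACA")
    for ves in vessels:
        cl = ves.centerline
        fracs = (0.5,) if ves.name in branch else (0.25, 0.5, 0.75)
        if isinstance(cl, StraightCenterline):
            p0 = np.asarray(cl.start)
            p1 = np.asarray(cl.end)
            tan = (p1 - p0) / np.linalg.norm(p1 - p0)
            for f in fracs:
                origin = p0 + f * (p1 - p0)
                planes.append(PlaneSpec(tuple(origin), tuple(tan),
                                        extent_mm=4.0 * ves.radius_mm,
                                        vessel_name=ves.name))
        else:
            pts, tans = cl.sample(spacing=0.1)
            for f in fracs:
                i = int(f * (len(pts) - 1))
                planes.append(PlaneSpec(tuple(pts[i]), tuple(tans[i]),
                                        extent_mm=4.0 * ves.radius_mm,
                                        vessel_name=ves.name))

    return PhantomConfig(shape=shape, voxel_size_mm=voxel_size_mm,
                         n_frames=n_frames, vessels=vessels, planes=planes)
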