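"""k-t sampling design for variable spatial-resolution dual-venc (VSRDV) 4D flow MRI.

The low-venc (LV) acquisition is undersampled with a sheared k-t lattice
(PEAK-GRAPPA style) outside a fully sampled autocalibration (ACS) block.
The high-venc (HV) acquisition reuses the LV pattern but additionally
zero-fills the outermost corners of the phase-encode plane, lowering the HV
spatial resolution only.  Acceleration is accounted for by line counting:

    R_PEAK-GRAPPA = Nky*Nkz / Lines_LV
    R_ZF          = 2*Lines_LV / (Lines_LV + Lines_HV)
    R_total       = R_PEAK-GRAPPA * R_ZF

where ``Lines_LV = (Nky-ACSy)(Nkz-ACSz)/R + ACSy*ACSz`` in rectangular mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SamplingGeometry",
    "KtMask",
    "AccelerationReport",
    "build_lv_mask",
    "build_hv_mask",
    "acceleration_report",
    "scan_time",
]


@dataclass(frozen=True)
class SamplingGeometry:
    """Phase-encode-plane geometry of one dual-venc acquisition.

    Parameters
    ----------
    nky, nkz : int
        Matrix size in the phase-encode (ky) and partition (kz) directions.
    acs_y, acs_z : int
        Width of the centered, fully sampled autocalibration block.
    r : int
        Nominal lattice undersampling factor outside the ACS (>= 1).
    z : float
        Zero-fill fraction of the HV k-space, in [0, 1).
    elliptical : bool
        If True, positions outside the inscribed ellipse of the
        phase-encode plane are never acquired ("cut-corner" sampling).
    n_frames : int
        Number of cardiac timeframes.
    z_budget : str
        What z is a fraction of: "eq6" (the full rectangular budget over R,
        the printed closed form) or "removable" (the acquired non-ACS
        lines); see :func:`zero_fill_count`.
    """

    nky: int
    nkz: int
    acs_y: int
    acs_z: int
    r: int = 1
    z: float = 0.0
    elliptical: bool = False
    n_frames: int = 1
    z_budget: str = "eq6"

    def __post_init__(self):
        if self.z_budget not in ("eq6", "removable"):
            raise ValueError("z_budget must be 'eq6' or 'removable'")
        if self.nky < 1 or self.nkz < 1:
            raise ValueError("matrix dimensions must be positive")
        if not (0 < self.acs_y <= self.nky and 0 < self.acs_z <= self.nkz):
            raise ValueError("ACS block must fit inside the matrix")
        if self.r < 1:
            raise ValueError(f"acceleration factor R must be >= 1, got {self.r}")
        if not 0.0 <= self.z < 1.0:
            raise ValueError(f"zero-fill fraction z must be in [0, 1), got {self.z}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    # DC sits at index floor(N/2), matching the standard FFT layout.
    @property
    def center(self) -> tuple[int, int]:
        return self.nky // 2, self.nkz // 2

    def acs_bounds(self) -> tuple[int, int, int, int]:
        """(ky_lo, ky_hi, kz_lo, kz_hi) half-open bounds of the ACS block."""
        cy, cz = self.center
        ky_lo = cy - self.acs_y // 2
        kz_lo = cz - self.acs_z // 2
        return ky_lo, ky_lo + self.acs_y, kz_lo, kz_lo + self.acs_z

    def acs_block(self) -> np.ndarray:
        """Boolean (nky, nkz) map of the ACS block."""
        ky_lo, ky_hi, kz_lo, kz_hi = self.acs_bounds()
        blk = np.zeros((self.nky, self.nkz), dtype=bool)
        blk[ky_lo:ky_hi, kz_lo:kz_hi] = True
        return blk

    def normalized_radius(self) -> np.ndarray:
        """(2*dky/Nky)**2 + (2*dkz/Nkz)**2 per (ky, kz), offsets from DC."""
        cy, cz = self.center
        dky = (np.arange(self.nky) - cy) / (self.nky / 2.0)
        dkz = (np.arange(self.nkz) - cz) / (self.nkz / 2.0)
        return dky[:, None] ** 2 + dkz[None, :] ** 2


@dataclass
class KtMask:
    """Boolean acquisition pattern over (ky, kz, frame) for one venc image."""

    acquired: np.ndarray  # bool, (nky, nkz, n_frames)
    geometry: SamplingGeometry
    venc_role: str = "LV"

    def lines_per_frame(self) -> np.ndarray:
        """Number of acquired ky-kz lines in each timeframe."""
        return self.acquired.sum(axis=(0, 1))

    def mean_lines(self) -> float:
        return float(self.lines_per_frame().mean())


def _outside_band_indices(n: int, lo: int, hi: int) -> np.ndarray:
    """Indices outside the half-open [lo, hi) band, ascending."""
    idx = np.arange(n)
    return idx[(idx < lo) | (idx >= hi)]


def build_lv_mask(geom: SamplingGeometry) -> KtMask:
    """Build the LV k-t acquisition mask.

    The ACS block is acquired in every frame.  Outside the ACS bands (both
    ky and kz outside), a sheared lattice acquires one of every R positions,
    with the lattice phase advancing by one step per kz row and per frame so
    that every lattice position is acquired at least once over any R
    consecutive frames.  At R=1 the mask is fully sampled.
    """
    nky, nkz, nt = geom.nky, geom.nkz, geom.n_frames
    acquired = np.zeros((nky, nkz, nt), dtype=bool)

    if geom.r == 1:
        acquired[:] = True
    else:
        ky_lo, ky_hi, kz_lo, kz_hi = geom.acs_bounds()
        out_ky = _outside_band_indices(nky, ky_lo, ky_hi)
        out_kz = _outside_band_indices(nkz, kz_lo, kz_hi)
        rank_y = np.arange(out_ky.size)
        rank_z = np.arange(out_kz.size)
        for t in range(nt):
            phase = (rank_y[:, None] + rank_z[None, :] + t) % geom.r == 0
            sub = np.zeros((nky, nkz), dtype=bool)
            sub[np.ix_(out_ky, out_kz)] = phase
            acquired[:, :, t] = sub
        acquired[geom.acs_block()] = True

    if geom.elliptical:
        outside = geom.normalized_radius() > 1.0
        outside &= ~geom.acs_block()  # ACS is always fully sampled
        acquired[outside] = False

    return KtMask(acquired=acquired, geometry=geom, venc_role="LV")


def zero_fill_count(geom: SamplingGeometry) -> int:
    """Number of HV lines removed per frame.

    Two conventions for what the zero-fill fraction z refers to:

    * ``"eq6"`` — the fully sampled rectangular budget scaled by 1/R:
      K = round(z*Nky*Nkz/R), the printed closed form.  Under this reading
      large z can exceed the number of removable lines (it does for the
      reference scanner geometry at z >= 0.6), which then raises.
    * ``"removable"`` — the non-ACS lines actually acquired in the HV:
      K = round(z * (Lines_LV - ACSy*ACSz)).  Feasible for all z in [0, 1)
      and the only reading whose implied scan-time savings approach the
      reference protocol's (~33% vs the reported 34.8% at z = 80%).
    """
    if geom.z_budget == "eq6":
        return int(np.rint(geom.z * geom.nky * geom.nkz / geom.r))
    removable = closed_form_lines_lv(geom) - geom.acs_y * geom.acs_z
    return int(np.rint(geom.z * removable))


def _ranked_candidates(geom: SamplingGeometry, frame_mask: np.ndarray) -> np.ndarray:
    """Flat (ky*nkz + kz) indices of removable lines, outermost first.

    Removable = acquired in LV this frame and not in the ACS block.  Sorted
    by descending normalized radius; ties broken lexicographically on
    (|ky-offset|, |kz-offset|, ky, kz) for a deterministic, seed-free order.
    """
    removable = frame_mask & ~geom.acs_block()
    ky, kz = np.nonzero(removable)
    cy, cz = geom.center
    radius = geom.normalized_radius()[ky, kz]
    order = np.lexsort((kz, ky, np.abs(kz - cz), np.abs(ky - cy), -radius))
    return ky[order] * geom.nkz + kz[order]


def build_hv_mask(
    geom: SamplingGeometry,
    lv_mask: KtMask,
    alternate: bool = False,
) -> KtMask:
    """Build the HV mask by corner zero-filling of the LV pattern.

    Per frame, exactly ``K = round(z*Nky*Nkz/R)`` acquired non-ACS lines are
    removed, outermost corners first.  ACS lines are never removed.  With
    ``alternate=True`` the removed set alternates between two interleaved
    half-sets of the outermost 2K candidates on even/odd frames (K removals
    per frame either way).
    """
    # the LV pattern does not depend on z; require agreement on everything else
    if replace(lv_mask.geometry, z=0.0) != replace(geom, z=0.0):
        raise ValueError("lv_mask was built from a different geometry")
    k = zero_fill_count(geom)
    acquired = lv_mask.acquired.copy()
    if k == 0:
        return KtMask(acquired=acquired, geometry=geom, venc_role="HV")

    for t in range(geom.n_frames):
        cand = _ranked_candidates(geom, lv_mask.acquired[:, :, t])
        need = 2 * k if alternate else k
        if need > cand.size:
            raise ValueError(
                f"cannot zero-fill {need} lines in frame {t}: only "
                f"{cand.size} non-ACS acquired lines are removable"
            )
        if alternate:
            removed = cand[: 2 * k][t % 2 :: 2]
        else:
            removed = cand[:k]
        flat = acquired[:, :, t].reshape(-1)
        flat[removed] = False

    return KtMask(acquired=acquired, geometry=geom, venc_role="HV")


@dataclass
class AccelerationReport:
    """Line counts, acceleration factors and relative scan time.

    ``lines_*`` are per-frame line counts (frame-averaged where the lattice
    does not divide evenly).  ``model`` records whether the numbers come
    from the rectangular closed forms or from mask counting.
    """

    lines_fully_sampled: float
    lines_lv: float
    lines_hv: float
    r_peak_grappa: float
    r_zf: float
    r_total: float
    time_savings_vs_z0: float
    model: str = "rectangular-Eq8"
    scan_time_s: float | None = None

    def as_dict(self) -> dict:
        return {
            "lines_fully_sampled": self.lines_fully_sampled,
            "lines_lv": self.lines_lv,
            "lines_hv": self.lines_hv,
            "r_peak_grappa": self.r_peak_grappa,
            "r_zf": self.r_zf,
            "r_total": self.r_total,
            "time_savings_vs_z0": self.time_savings_vs_z0,
            "model": self.model,
            "scan_time_s": self.scan_time_s,
        }


def closed_form_lines_lv(geom: SamplingGeometry) -> float:
    """Per-frame LV line count from the rectangular closed form."""
    if geom.r == 1:
        return float(geom.nky * geom.nkz)
    return (geom.nky - geom.acs_y) * (geom.nkz - geom.acs_z) / geom.r + geom.acs_y * geom.acs_z


def acceleration_report(geom: SamplingGeometry) -> AccelerationReport:
    """Compute all acceleration factors for a geometry.

    Rectangular mode uses the closed forms; elliptical mode counts lines on
    the generated masks.  In rectangular mode the closed forms equal the
    mask counts exactly whenever R divides (Nky-ACSy)(Nkz-ACSz).
    """
    full = float(geom.nky * geom.nkz)
    if geom.elliptical:
        lv = build_lv_mask(geom)
        hv = build_hv_mask(geom, lv)
        lines_lv = lv.mean_lines()
        lines_hv = hv.mean_lines()
        model = "elliptical-mask-count"
    else:
        lines_lv = closed_form_lines_lv(geom)
        lines_hv = lines_lv - zero_fill_count(geom)
        if lines_hv < geom.acs_y * geom.acs_z:
            # surface the same infeasibility the mask builder would hit
            build_hv_mask(geom, build_lv_mask(geom))
        model = ("rectangular-Eq8" if geom.z_budget == "eq6"
                 else "rectangular-removable-budget")

    r_pg = full / lines_lv
    r_zf = 1.0 if geom.z == 0 else 2.0 * lines_lv / (lines_lv + lines_hv)
    return AccelerationReport(
        lines_fully_sampled=full,
        lines_lv=lines_lv,
        lines_hv=lines_hv,
        r_peak_grappa=r_pg,
        r_zf=r_zf,
        r_total=r_pg * r_zf,
        time_savings_vs_z0=1.0 - 1.0 / r_zf,
        model=model,
    )


def scan_time(
    report: AccelerationReport,
    pulse_interval: float,
    n_frames: int | None = None,
) -> float:
    """Scan time in seconds for a dual-venc acquisition.

    One heartbeat fills one 8xTR slot per LV/HV line pair across all cardiac
    frames, and a slot whose HV line is zero-filled carries two LV lines, so
    heartbeats = (Lines_LV + Lines_HV)/2.  ``n_frames`` is accepted for
    interface symmetry; the per-heartbeat slot already spans all frames.
    """
    if pulse_interval <= 0:
        raise ValueError("pulse interval must be positive")
    heartbeats = (report.lines_lv + report.lines_hv) / 2.0
    return heartbeats * pulse_interval


def report_with_scan_time(
    geom: SamplingGeometry, pulse_interval: float
) -> AccelerationReport:
    rep = acceleration_report(geom)
    return replace(rep, scan_time_s=scan_time(rep, pulse_interval))
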