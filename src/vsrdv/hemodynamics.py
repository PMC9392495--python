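"""Quantification chain: background-phase correction, PCMRA masking,
plane-wise velocimetry, Bland-Altman agreement and test-retest repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import PlaneSpec
from .recon import VelocityVolume

__all__ = [
    "PlaneStats",
    "AgreementResult",
    "background_phase_correct",
    "pcmra",
    "make_roi_mask",
    "plane_quantify",
    "bland_altman",
    "repeatability_coefficient",
]


@dataclass
class PlaneStats:
    """Per-frame mean/peak through-plane velocity and lumen area at a plane."""

    plane: PlaneSpec
    mean_velocity: np.ndarray   # (nt,), cm/s
    peak_velocity: np.ndarray   # (nt,), cm/s
    area_mm2: float
    mean_ta: float              # time-averaged mean velocity
    peak_ta: float              # time-averaged peak velocity


@dataclass
class AgreementResult:
    """Bland-Altman agreement between paired measurements.

    ``loa_*`` are bias +/- 1.96*sd of the paired differences;
    ``trend_slope`` is the regression slope of the differences on the pair
    means (a proportional-error trend; the intercept is reported alongside
    since conventions differ).  Percentages are relative to the mean of the
    reference values.  ``rpc`` (1.96*sd of session differences) is filled by
    :func:`repeatability_coefficient`.
    """

    n: int
    bias: float
    bias_p: float
    loa_lower: float
    loa_upper: float
    bias_pct_ref: float
    loa_lower_pct: float
    loa_upper_pct: float
    trend_slope: float
    trend_slope_p: float
    trend_intercept: float
    rpc: float | None = None
    rpc_pct_session1: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "bias", "bias_p", "loa_lower", "loa_upper", "bias_pct_ref",
            "loa_lower_pct", "loa_upper_pct", "trend_slope", "trend_slope_p",
            "trend_intercept", "rpc", "rpc_pct_session1")}


def background_phase_correct(
    vel: VelocityVolume,
    static_mask: np.ndarray,
    per_frame: bool = False,
) -> VelocityVolume:
    """Subtract a first-order background phase fitted on static tissue.

    Per direction, a0 + a1*x + a2*y + a3*z is least-squares fitted to the
    (by default time-averaged) velocity over static voxels and subtracted
    from the entire volume.  Idempotent to numerical tolerance.  Raises on
    degenerate static geometry (fewer than 4 voxels or coplanar voxels).
    """
    n_static = int(np.count_nonzero(static_mask))
    if n_static < 4:
        raise ValueError("need at least 4 static voxels for a first-order fit")
    nx, ny, nz = static_mask.shape
    gx, gy, gz = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij")
    design_full = np.stack(
        [np.ones(nx * ny * nz), gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    a = design_full[static_mask.ravel()]
    if np.linalg.matrix_rank(a) < 4:
        raise ValueError("static voxels are coplanar; background fit is degenerate")

    corrected = vel.velocity.copy()
    nt = vel.velocity.shape[-1]
    for d in range(3):
        if per_frame:
            for t in range(nt):
                b = vel.velocity[d, ..., t].reshape(-1)[static_mask.ravel()]
                coef, *_ = np.linalg.lstsq(a, b, rcond=None)
                corrected[d, ..., t] -= (design_full @ coef).reshape(nx, ny, nz)
        else:
            b = vel.velocity[d].mean(axis=-1).reshape(-1)[static_mask.ravel()]
            coef, *_ = np.linalg.lstsq(a, b, rcond=None)
            corrected[d] -= (design_full @ coef).reshape(nx, ny, nz)[..., None]
    return vel.copy_with(velocity=corrected.astype(np.float32))


def pcmra(magnitude: np.ndarray, vel: VelocityVolume) -> np.ndarray:
    """Pseudo-complex-difference PC-MR angiogram.

    sqrt( (1/Nt) * sum_t M(t)^2 * (vx^2 + vy^2 + vz^2)(t) ), a 3D map that
    vanishes in static tissue and scales linearly with the magnitude.
    """
    v2 = np.sum(vel.velocity.astype(np.float64) ** 2, axis=0)
    return np.sqrt(np.mean(magnitude.astype(np.float64) ** 2 * v2, axis=-1))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (xx**2 + yy**2 + zz**2) <= r**2


def make_roi_mask(pcmra_map: np.ndarray, threshold: float = 0.15,
                  erosion_voxels: int = 2, min_component: int = 0) -> np.ndarray:
    """Threshold the PCMRA at a fraction of its max, then erode.

    ``min_component`` drops connected components smaller than that many
    voxels before eroding — a stand-in for the manual cleanup of an
    angiogram segmentation, which removes isolated noise speckle that a
    plain threshold keeps.  Erosion by a ball of the given radius keeps the
    evaluation away from lumen boundaries, where partial-volume voxels
    would produce spurious aliasing comparisons.  Raises if the mask is
    empty after erosion.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if erosion_voxels < 0:
        raise ValueError("erosion radius must be >= 0")
    mask = pcmra_map >= threshold * pcmra_map.max()
    if min_component > 0:
        labels, _ = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = np.isin(labels, np.nonzero(sizes >= min_component)[0])
    if erosion_voxels > 0:
        mask = ndimage.binary_erosion(mask, structure=_ball(erosion_voxels))
    if not np.any(mask):
        raise ValueError("ROI mask is empty after erosion")
    return mask


def plane_quantify(
    vel: VelocityVolume,
    lumen_mask: np.ndarray,
    plane: PlaneSpec,
    pixel_mm: float = 0.25,
) -> PlaneStats:
    """Resample velocity onto a plane and quantify through-plane flow.

    The velocity components and the lumen mask are trilinearly sampled onto
    a 2D grid (default 0.25 mm spacing) spanning the plane extent; pixels
    with interpolated mask >= 0.5 form the lumen.  Per frame, the mean and
    maximum of the through-plane component (v . normal) over lumen pixels
    are reported; the area is the lumen pixel count times the pixel area.
    """
    origin = np.asarray(plane.origin, float)
    normal = np.asarray(plane.normal, float)
    # in-plane orthonormal basis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    half = plane.extent_mm / 2.0
    ab = np.arange(-half, half + pixel_mm / 2, pixel_mm)
    aa, bb = np.meshgrid(ab, ab, indexing="ij")
    pts = (origin[None, :] + aa.reshape(-1, 1) * e1[None, :]
           + bb.reshape(-1, 1) * e2[None, :])
    idx = (pts / vel.voxel_size_mm).T  # (3, npix) voxel-index coordinates

    lum = ndimage.map_coordinates(lumen_mask.astype(np.float32), idx,
                                  order=1, mode="constant", cval=0.0)
    inside = lum >= 0.5
    if not np.any(inside):
        raise ValueError("plane does not intersect the lumen mask")
    idx_in = idx[:, inside]

    nt = vel.velocity.shape[-1]
    mean_v = np.empty(nt)
    peak_v = np.empty(nt)
    for t in range(nt):
        through = np.zeros(idx_in.shape[1])
        for d in range(3):
            through += normal[d] * ndimage.map_coordinates(
                vel.velocity[d, ..., t], idx_in, order=1, mode="constant",
                cval=0.0)
        mean_v[t] = through.mean()
        # signed extremum: reversing the plane normal negates the peak
        peak_v[t] = through[np.argmax(np.abs(through))]

    return PlaneStats(
        plane=plane,
        mean_velocity=mean_v,
        peak_velocity=peak_v,
        area_mm2=float(np.count_nonzero(inside) * pixel_mm**2),
        mean_ta=float(mean_v.mean()),
        peak_ta=float(peak_v.mean()),
    )


def bland_altman(reference, test) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    d = test - reference; bias = mean(d); LOA = bias +/- 1.96*sd(d) (sample
    sd); the bias p-value is a two-sided one-sample t-test of d against 0;
    the proportional trend is the regression of d on the pair means.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1D sequences")
    n = ref.size
    if n < 3:
        raise ValueError("need at least 3 paired values")

    d = tst - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd > 0:
        bias_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        bias_p = float("nan")
    mean_pair = (tst + ref) / 2.0
    if np.ptp(mean_pair) > 0:
        reg = stats.linregress(mean_pair, d)
        slope, slope_p, intercept = float(reg.slope), float(reg.pvalue), float(reg.intercept)
    else:
        slope, slope_p, intercept = 0.0, float("nan"), bias
    mref = float(np.mean(ref))
    scale = 100.0 / mref if mref != 0 else float("nan")
    return AgreementResult(
        n=n, bias=bias, bias_p=bias_p,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        bias_pct_ref=bias * scale,
        loa_lower_pct=(bias - 1.96 * sd) * scale,
        loa_upper_pct=(bias + 1.96 * sd) * scale,
        trend_slope=slope, trend_slope_p=slope_p, trend_intercept=intercept,
    )


def repeatability_coefficient(session1, session2) -> AgreementResult:
    """Test-retest repeatability: RPC = 1.96 * sd(session2 - session1).

    Returned inside an :class:`AgreementResult` with ``rpc`` and
    ``rpc_pct_session1`` (percentage of the first-session mean) filled.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    res = bland_altman(s1, s2)
    sd = float(np.std(s2 - s1, ddof=1))
    rpc = 1.96 * sd
    m1 = float(np.mean(s1))
    res.rpc = rpc
    res.rpc_pct_session1 = 100.0 * rpc / m1 if m1 != 0 else float("nan")
    return res
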