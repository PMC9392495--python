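"""Eight-point dual-venc encoding and multi-coil k-space simulation.

Per cardiac timeframe, a phase reference plus three orthogonal flow encodes
are produced for each of the low-venc (LV) and high-venc (HV) images — eight
encodings per frame.  A flow encode along direction ``d`` adds a phase of
``pi * v_d / venc`` to the reference phase; signal magnitude comes from the
phantom.  Multi-coil k-space is the orthonormal 3D Fourier transform of the
coil-weighted images, sampled on a k-t mask with i.i.d. complex Gaussian
noise on the acquired samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .phantom import FlowPhantom
from .sampling import KtMask

__all__ = [
    "EncodingScheme",
    "CoilKspace",
    "encode_images",
    "coil_sensitivities",
    "simulate_kspace",
    "kspace_of_images",
]


@dataclass(frozen=True)
class EncodingScheme:
    """Eight-point interleaved dual-venc encoding scheme.

    Encodings 0-3 are the LV reference and x/y/z flow encodes, 4-7 the HV
    set; on the scanner the LV and HV lines are interleaved within each
    cardiac timeframe (8xTR temporal resolution).  ``venc_high`` must equal
    ``2 * venc_low`` — the unwrapping substitution bands assume that ratio.
    """

    venc_low: float = 55.0
    venc_high: float = 110.0
    first_moment_sign: tuple[int, ...] = (1,) * 8

    def __post_init__(self):
        if self.venc_low <= 0:
            raise ValueError("venc_low must be positive")
        if not np.isclose(self.venc_high, 2.0 * self.venc_low):
            raise ValueError("venc_high must equal 2 * venc_low")
        if len(self.first_moment_sign) != 8:
            raise ValueError("eight first-moment signs required")

    @property
    def points(self) -> list[tuple[str, int | None, float]]:
        """(role, flow direction or None, venc) for each of the 8 encodings."""
        out = []
        for role, venc in (("LV", self.venc_low), ("HV", self.venc_high)):
            out.append((role, None, venc))
            for d in range(3):
                out.append((role, d, venc))
        return out

    def lv_indices(self) -> list[int]:
        return [0, 1, 2, 3]

    def hv_indices(self) -> list[int]:
        return [4, 5, 6, 7]


def linear_phase_field(shape: tuple[int, int, int],
                       coeffs: tuple[float, float, float, float] = (0.3, 0.25, -0.2, 0.15),
                       ) -> np.ndarray:
    """First-order background phase a0 + a1*u + a2*v + a3*w, u,v,w in [-1,1]."""
    nx, ny, nz = shape
    u = np.linspace(-1, 1, nx)[:, None, None]
    v = np.linspace(-1, 1, ny)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    a0, a1, a2, a3 = coeffs
    return (a0 + a1 * u + a2 * v + a3 * w).astype(np.float32)


def encode_images(
    phantom: FlowPhantom,
    scheme: EncodingScheme,
    encoding: int | None = None,
    background_phase: np.ndarray | None = None,
    eddy_phase: dict[int, np.ndarray] | None = None,
    dtype=np.complex64,
) -> np.ndarray:
    """Complex encoded images, (n_enc, nx, ny, nz, nt), complex64.

    The reference encoding carries the background phase field phi0; flow
    encode ``d`` adds ``sign * pi * v_d / venc``.  ``eddy_phase`` maps an
    encoding index to an extra (non-velocity) phase field that does not
    cancel in the phase difference — used to exercise the first-order
    background correction.  ``encoding`` selects a single encoding.
    """
    shape = phantom.config.shape
    nt = phantom.config.n_frames
    if background_phase is None:
        background_phase = linear_phase_field(shape)
    phi0 = background_phase[..., None]  # broadcast over frames

    indices = list(range(8)) if encoding is None else [encoding]
    ftype = np.float32 if dtype == np.complex64 else np.float64
    out = np.empty((len(indices), *shape, nt), dtype=dtype)
    for j, e in enumerate(indices):
        role, d, venc = scheme.points[e]
        phase = np.broadcast_to(phi0, (*shape, nt)).astype(ftype).copy()
        if d is not None:
            sign = scheme.first_moment_sign[e]
            phase += sign * np.pi * phantom.velocity[d].astype(ftype) / venc
        if eddy_phase and e in eddy_phase:
            phase += eddy_phase[e][..., None]
        out[j] = phantom.magnitude * np.exp(1j * phase)
    return out


def coil_sensitivities(n_coils: int, shape: tuple[int, int, int],
                       seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps, (n_coils, nx, ny, nz), RSS-normalized to 1.

    Gaussian lobes are placed on a ring around the volume with a mild linear
    phase per coil; ``n_coils=1`` returns a constant unit map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = shape
    if n_coils == 1:
        return np.ones((1, nx, ny, nz), dtype=np.complex64)

    rng = np.random.default_rng(seed)
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    sens = np.empty((n_coils, nx, ny, nz), dtype=np.complex64)
    width = 0.8
    # head-coil-like array: two stacked rings (staggered azimuthally) so the
    # maps vary along all three axes — the sheared lattice aliases in both
    # phase-encode directions and needs z diversity as well
    two_rings = n_coils >= 4
    per_ring = (n_coils + 1) // 2 if two_rings else n_coils
    for c in range(n_coils):
        ring = c % 2 if two_rings else 0
        k = c // 2 if two_rings else c
        ang = 2 * np.pi * k / per_ring + (np.pi / per_ring) * ring + rng.normal(0, 0.05)
        cx, cy = 1.1 * np.cos(ang), 1.1 * np.sin(ang)
        cz = (-0.6, 0.6)[ring] if two_rings else 0.0
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + 0.8 * (z - cz) ** 2)
                     / (2 * width**2))
        ph = (rng.normal(0, 0.8) * x + rng.normal(0, 0.8) * y
              + rng.normal(0, 0.6) * z + rng.uniform(0, 2 * np.pi))
        sens[c] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0, keepdims=True))
    return (sens / rss).astype(np.complex64)


@dataclass
class CoilKspace:
    """Masked multi-coil k-space for a set of encodings.

    ``data`` has shape (n_coils, n_enc, nx, nky, nkz, nt) with k-space
    centered (DC at index N//2 on each axis).  Non-acquired (ky, kz, frame)
    positions are exactly zero.  ``noise_sd`` is the standard deviation per
    real/imaginary component added to acquired samples.
    """

    data: np.ndarray
    mask: KtMask
    noise_sd: float
    seed: int
    encoding_indices: tuple[int, ...] = ()


def kspace_of_images(images: np.ndarray) -> np.ndarray:
    """Centered orthonormal 3D FFT over the spatial axes (-4, -3, -2).

    scipy.fft preserves complex64, keeping the multi-coil arrays compact.
    """
    axes = (-4, -3, -2)
    return spfft.fftshift(
        spfft.fftn(spfft.ifftshift(images, axes=axes), axes=axes, norm="ortho"),
        axes=axes)


def images_of_kspace(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`kspace_of_images`."""
    axes = (-4, -3, -2)
    return spfft.fftshift(
        spfft.ifftn(spfft.ifftshift(ksp, axes=axes), axes=axes, norm="ortho"),
        axes=axes)


def simulate_kspace(
    images: np.ndarray,
    sens: np.ndarray,
    mask: KtMask,
    noise_sd: float = 0.0,
    seed: int = 0,
    encoding_indices: tuple[int, ...] = (),
) -> CoilKspace:
    """Sample coil-weighted k-space of ``images`` on a k-t mask.

    ``images``: (n_enc, nx, ny, nz, nt) complex; ``sens``: (n_coils, nx, ny,
    nz).  Noise is i.i.d. complex Gaussian (sd per component) on acquired
    samples only; deterministic for a fixed seed.
    """
    if images.shape[2] != mask.acquired.shape[0] or images.shape[3] != mask.acquired.shape[1]:
        raise ValueError("mask geometry does not match image grid (ky=ny, kz=nz)")
    if images.shape[4] != mask.acquired.shape[2]:
        raise ValueError("mask frame count does not match images")

    weighted = (sens.astype(images.dtype)[:, None, :, :, :, None] * images[None])
    ksp = kspace_of_images(weighted).astype(images.dtype)
    ksp = apply_mask_and_noise(ksp, mask, noise_sd, seed)
    return CoilKspace(data=ksp, mask=mask, noise_sd=noise_sd, seed=seed,
                      encoding_indices=tuple(encoding_indices))


def apply_mask_and_noise(ksp: np.ndarray, mask: KtMask, noise_sd: float,
                         seed: int = 0) -> np.ndarray:
    """Mask full k-space and add complex Gaussian noise to acquired samples.

    The noise realization depends only on the seed and the array shape, so
    re-running with a scaled ``noise_sd`` scales the same realization —
    convenient for noise calibration.
    """
    m = mask.acquired[None, None, None, :, :, :]
    out = ksp.copy()
    if noise_sd > 0:
        ftype = np.float32 if out.dtype == np.complex64 else np.float64
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(*out.shape, 2)).astype(ftype)
        out += noise[..., 0] + 1j * noise[..., 1]
    out *= m
    return out
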