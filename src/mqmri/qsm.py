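"""Quantitative susceptibility mapping chain.

Field estimation from complex multiecho GRE data (nonlinear per-voxel fit),
Laplacian phase unwrapping, V-SHARP background-field removal, and
Tikhonov-regularized dipole inversion.  The forward dipole convolution used
by the simulator lives here too, so forward and inverse models share one
kernel definition.

All spectral operators use FFTs with periodic boundary conditions; a
three-voxel boundary band is always eroded from quantitative masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .relaxometry import MultiEchoGRE

__all__ = [
    "FieldMap",
    "SusceptibilityMap",
    "dipole_kernel",
    "dipole_field",
    "fit_fieldmap",
    "laplacian_unwrap",
    "vsharp_filter",
    "invert_susceptibility",
]


@dataclass
class FieldMap:
    """Off-resonance field in Hz with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite field inside the valid mask")


@dataclass
class SusceptibilityMap:
    """Susceptibility in ppm, mean-zero over its (eroded) mask."""

    values: np.ndarray
    mask: np.ndarray
    converged: bool = True
    info: dict = field(default_factory=dict)


def dipole_kernel(
    shape: Sequence[int],
    b0_direction: Sequence[float] = (0.0, 0.0, 1.0),
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """k-space dipole kernel D(k) = 1/3 - (k.b)^2 / |k|^2, with D(0) = 0.

    The k = 0 singularity is resolved by the mean-field reference
    convention: the uniform component of chi produces no internal field
    contrast, so D(0) is set to 0.
    """
    b = np.asarray(b0_direction, dtype=float)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("b0_direction must have nonzero norm")
    b = b / nb
    ks = [np.fft.fftfreq(n, d=dx) for n, dx in zip(shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - (kb**2) / k2
    d[k2 == 0] = 0.0
    return d


def dipole_field(
    chi: np.ndarray,
    b0_direction: Sequence[float] = (0.0, 0.0, 1.0),
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Forward dipole convolution: field (ppm of B0) from chi (ppm).

    Odd-sized axes are zero-padded to even length for the FFT and cropped
    back, so the caller never sees the padding.
    """
    chi = np.asarray(chi, dtype=float)
    pads = [(0, n % 2) for n in chi.shape]
    padded = np.pad(chi, pads) if any(p[1] for p in pads) else chi
    d = dipole_kernel(padded.shape, b0_direction, voxel_size)
    out = np.fft.ifftn(d * np.fft.fftn(padded)).real
    return out[tuple(slice(0, n) for n in chi.shape)]


def _concentrated_objective(data: np.ndarray, te_s: np.ndarray, f: np.ndarray):
    """|S(f)|^2 and its first two derivatives, where
    S(f) = sum_j s_j exp(-i 2 pi f TE_j).  Maximizing |S|^2 over f is the
    least-squares fit of s_j = a exp(i phi0 + i 2 pi f TE_j) with (a, phi0)
    profiled out."""
    w = np.exp(-2j * np.pi * f[..., None] * te_s)
    s0 = np.sum(data * w, axis=-1)
    s1 = np.sum(data * w * (-2j * np.pi * te_s), axis=-1)
    s2 = np.sum(data * w * (-2j * np.pi * te_s) ** 2, axis=-1)
    j0 = np.abs(s0) ** 2
    j1 = 2.0 * np.real(np.conj(s0) * s1)
    j2 = 2.0 * (np.abs(s1) ** 2 + np.real(np.conj(s0) * s2))
    return j0, j1, j2, s0


def fit_fieldmap(
    gre: MultiEchoGRE, residual_flag_threshold: float = 0.25
) -> tuple[FieldMap, np.ndarray]:
    """Per-voxel nonlinear least-squares field estimate from complex echoes.

    The model is s_j = a * exp(i phi0 + i 2 pi f TE_j); amplitude and offset
    phase are profiled out analytically and f is polished by Newton
    iterations from the echo-1/2 phase-difference initializer.  With equally
    spaced echoes f is identifiable only modulo 1/dTE; the estimate is
    reported in the principal interval around the initializer.

    Returns the field map (Hz) and a normalized residual map (fit RMS
    residual / signal RMS); voxels with zero magnitude are masked out,
    voxels whose residual exceeds ``residual_flag_threshold`` are excluded
    from the valid mask (noise voxels).
    """
    data = gre.data
    if data.ndim != 4:
        raise ValueError("fit_fieldmap expects single-channel (x, y, z, echo) data")
    if data.shape[-1] < 3:
        raise ValueError("need at least three echoes")
    te_s = gre.echo_times * 1e-3
    mag = np.abs(data)
    mask = mag.mean(axis=-1) > 0

    f = np.zeros(data.shape[:-1])
    dte12 = te_s[1] - te_s[0]
    f[mask] = np.angle(data[mask][:, 1] * np.conj(data[mask][:, 0])) / (
        2.0 * np.pi * dte12
    )
    sub = data[mask]
    fm = f[mask]
    max_step = 0.25 / dte12
    for _ in range(30):
        _, j1, j2, _ = _concentrated_objective(sub, te_s, fm)
        step = np.where(j2 < 0, -j1 / j2, j1 * 0.0)
        step = np.clip(step, -max_step, max_step)
        fm = fm + step
        if np.max(np.abs(step), initial=0.0) < 1e-12:
            break
    f[mask] = fm

    residual = np.ones(data.shape[:-1])
    j0, _, _, s0 = _concentrated_objective(sub, te_s, fm)
    n_echo = te_s.size
    sig2 = np.sum(np.abs(sub) ** 2, axis=-1)
    res2 = np.clip(sig2 - j0 / n_echo, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        residual[mask] = np.sqrt(res2 / sig2)
    valid = mask & (residual <= residual_flag_threshold)
    return FieldMap(np.where(mask, f, 0.0), valid), residual


def _k2(shape: Sequence[int]) -> np.ndarray:
    ks = [2.0 * np.pi * np.fft.fftfreq(n) for n in shape]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    return kx**2 + ky**2 + kz**2


def _laplacian(u: np.ndarray, k2: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(-k2 * np.fft.fftn(u)).real


def laplacian_unwrap(phase: np.ndarray) -> np.ndarray:
    """Laplacian phase unwrapping via an FFT Poisson solve.

    Solves lap(psi) = cos(phi) lap(sin(phi)) - sin(phi) lap(cos(phi)) with a
    zeroed DC term; the output matches the true phase up to a harmonic
    (slowly varying) component, which the background-removal step absorbs.
    """
    phase = np.asarray(phase, dtype=float)
    k2 = _k2(phase.shape)
    rhs = np.cos(phase) * _laplacian(np.sin(phase), k2) - np.sin(phase) * _laplacian(
        np.cos(phase), k2
    )
    rhs_k = np.fft.fftn(rhs)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_k = rhs_k / (-k2)
    psi_k[k2 == 0] = 0.0
    return np.fft.ifftn(psi_k).real


def _sphere_kernel_fft(shape: Sequence[int], radius: float) -> np.ndarray:
    """FFT of a normalized spherical-mean kernel of the given voxel radius,
    built centered at the origin with periodic wrap."""
    grids = []
    for n in shape:
        idx = np.arange(n, dtype=float)
        idx = np.minimum(idx, n - idx)
        grids.append(idx)
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    ball = (gx**2 + gy**2 + gz**2) <= radius**2 + 1e-9
    kern = ball / ball.sum()
    return np.fft.fftn(kern)


def _erode(mask: np.ndarray, kernel_fft: np.ndarray) -> np.ndarray:
    conv = np.fft.ifftn(kernel_fft * np.fft.fftn(mask.astype(float))).real
    return conv > 1.0 - 1e-6


def vsharp_filter(
    fieldmap: FieldMap | np.ndarray,
    mask: np.ndarray,
    radii: Sequence[int] = (3, 2, 1),
    threshold: float = 0.05,
    boundary_erosion: int = 3,
) -> tuple[FieldMap, np.ndarray]:
    """V-SHARP background-field removal.

    Spherical-mean-value (SMV) filtering removes any field that is harmonic
    inside the mask (i.e., generated by sources outside it).  The kernel
    radius shrinks toward the mask boundary (variable-kernel SHARP); the
    remaining high-pass field is deconvolved by the largest kernel with a
    truncated inverse filter, and the mask is eroded by ``boundary_erosion``
    voxels in the returned map.
    """
    f = fieldmap.values if isinstance(fieldmap, FieldMap) else np.asarray(fieldmap, float)
    mask = mask.astype(bool)
    radii = sorted(set(int(r) for r in radii), reverse=True)
    if radii[-1] < 1:
        raise ValueError("kernel radii must be >= 1 voxel")
    f = f * mask
    fk = np.fft.fftn(f)

    high_pass = np.zeros_like(f)
    assigned = np.zeros(f.shape, dtype=bool)
    kern_max = None
    for r in radii:
        kfft = _sphere_kernel_fft(f.shape, r)
        if kern_max is None:
            kern_max = kfft
            if not _erode(mask, kfft).any():
                raise ValueError("mask is smaller than the largest V-SHARP kernel")
        smv = np.fft.ifftn(kfft * fk).real
        sel = _erode(mask, kfft) & ~assigned
        high_pass[sel] = (f - smv)[sel]
        assigned |= sel

    denom = 1.0 - kern_max
    inv = np.where(np.abs(denom) > threshold, 1.0 / np.where(denom == 0, 1.0, denom), 0.0)
    local = np.fft.ifftn(inv * np.fft.fftn(high_pass * assigned)).real

    ero_fft = _sphere_kernel_fft(f.shape, boundary_erosion)
    out_mask = _erode(mask, ero_fft) & assigned
    return FieldMap(np.where(out_mask, local, 0.0), out_mask), out_mask


def invert_susceptibility(
    local_field: FieldMap | np.ndarray,
    mask: np.ndarray,
    reg_param: float = 1e-3,
    hz_per_ppm: float | None = None,
    b0_direction: Sequence[float] = (0.0, 0.0, 1.0),
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    max_iter: int = 300,
    tol: float = 1e-8,
) -> SusceptibilityMap:
    """Masked Tikhonov-regularized dipole inversion by conjugate gradients.

    Solves argmin_chi || M (F^-1 D F (M chi) - f) ||^2 + lambda ||chi||^2
    where M is the (eroded) brain mask and D the dipole kernel; after
    background-field removal all remaining sources are assumed to lie inside
    the mask, so the unknowns are restricted to its support.  The result is
    referenced to mean zero over the mask.  ``hz_per_ppm`` converts a field
    map given in Hz to ppm (pass None if the input is already in ppm).
    """
    if reg_param < 0:
        raise ValueError("regularization parameter must be >= 0")
    f = local_field.values if isinstance(local_field, FieldMap) else np.asarray(local_field, float)
    if hz_per_ppm is not None:
        f = f / hz_per_ppm
    mask = mask.astype(bool)
    d = dipole_kernel(f.shape, b0_direction, voxel_size)

    def fwd(x):
        return np.fft.ifftn(d * np.fft.fftn(x * mask)).real * mask

    adj = fwd  # the masked dipole operator is self-adjoint (D real, symmetric)

    b = adj(f * mask)
    x = np.zeros_like(f)
    if not np.any(b):
        return SusceptibilityMap(x, mask, True, {"iterations": 0, "reg_param": reg_param})
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.sqrt(np.vdot(b, b).real) or 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ap = adj(fwd(p)) + reg_param * p
        alpha = rs / np.vdot(p, ap).real
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) / b_norm < tol:
            converged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    x = x - x[mask].mean() if mask.any() else x
    x = np.where(mask, x, 0.0)
    return SusceptibilityMap(
        x, mask, converged, {"iterations": n_iter, "reg_param": reg_param}
    )
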