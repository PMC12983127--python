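"""CEST quantification: WASSR B0 mapping, Z-spectrum normalization and B0
correction, two-stage five-pool Lorentzian/super-Lorentzian fitting, and
AREX map computation.

Fitting strategy
----------------
The five-pool model (direct water saturation, semisolid MT, amide +3.5 ppm,
amine +2.0 ppm, relayed NOE -3.5 ppm) is fitted in two stages per voxel:

1. The MT baseline (water + MT parameters) is estimated from Z-spectrum
   points strictly outside the +/-8 ppm band, where the sharp solute pools
   contribute negligibly.  This keeps the broad MT line from absorbing NOE
   signal.
2. The full spectrum is refit jointly, seeded from the stage-1 estimates,
   with a multi-start guard against the local minima in which the NOE pool
   swaps roles with the water or MT line (a stage-1 MT amplitude from ten
   far points alone is too noisy to freeze outright).

All parameters are constrained to the bounds table in
:mod:`mqmri.lineshapes`; fitted values can never leave it.  The -300 ppm
reference acquisition is used only for normalization and never enters a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .lineshapes import (
    POOL_BOUNDS,
    PoolParameterSet,
    lorentzian_eval,
    super_lorentzian_eval,
)
from .relaxometry import QuantMap

__all__ = [
    "CESTGeometry",
    "ZSpectrumStack",
    "B0Map",
    "PoolFitResult",
    "FivePoolModel",
    "wassr_b0_map",
    "normalize_and_correct",
    "fit_mt_baseline",
    "fit_five_pool",
    "compute_arex",
    "resample_to_cest",
    "lorentzian_eval",
    "super_lorentzian_eval",
]

MT_EXCLUSION_PPM = 8.0  # solute-free band boundary for the MT baseline fit
_RESTART_RMS = 3e-3  # stage-2 residual above this triggers a fresh-start retry


@dataclass(frozen=True)
class CESTGeometry:
    """Multislice 2-D CEST slab geometry (slices along the third axis)."""

    n_slices: int = 8
    slice_thickness_mm: float = 0.25
    slice_gap_mm: float = 0.25
    z0_mm: float = 0.0  # bottom face of the first slice

    @property
    def slice_centers_mm(self) -> np.ndarray:
        pitch = self.slice_thickness_mm + self.slice_gap_mm
        return self.z0_mm + self.slice_thickness_mm / 2.0 + pitch * np.arange(
            self.n_slices
        )


@dataclass
class ZSpectrumStack:
    """Per-voxel normalized saturation spectra.

    ``z`` has shape (x, y, slice, offset); ``offsets`` (ppm) matches the last
    axis and never contains the reference offset.  ``reference_image`` is the
    unsaturated acquisition used for normalization.  Normalized spectra are
    expected in [0, 1.2]; a small overshoot above 1 is tolerated but larger
    values are rejected.
    """

    z: np.ndarray
    offsets: np.ndarray
    reference_image: np.ndarray | None = None
    geometry: CESTGeometry = field(default_factory=CESTGeometry)
    flags: np.ndarray | None = None  # per-voxel quality flags

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.z.shape[-1] != self.offsets.size:
            raise ValueError("offset axis does not match offsets list")
        if np.nanmax(self.z, initial=0.0) > 1.2 or np.nanmin(self.z, initial=0.0) < -1e-9:
            raise ValueError("normalized Z values outside [0, 1.2]")


@dataclass
class B0Map:
    """Per-voxel water-center offset (ppm) from WASSR."""

    values: np.ndarray
    valid_mask: np.ndarray
    method: str = "wassr-spline-minimum"


def wassr_b0_map(wassr: ZSpectrumStack, grid_step_ppm: float = 0.001) -> B0Map:
    """B0 offset map by water shift referencing.

    Each voxel's WASSR spectrum is interpolated with a cubic spline onto a
    fine grid (default 0.001 ppm) and the location of the interpolated
    minimum is taken as the local water-center offset.  Voxels with flat
    spectra (no minimum) are masked out.
    """
    offs = wassr.offsets
    if offs.min() > -1.0 + 1e-9 or offs.max() < 1.0 - 1e-9:
        raise ValueError("WASSR offsets must span -1..1 ppm")
    order = np.argsort(offs)
    fine = np.arange(offs.min(), offs.max() + grid_step_ppm / 2, grid_step_ppm)
    flat_shape = wassr.z.shape[:-1]
    values = np.zeros(flat_shape)
    valid = np.zeros(flat_shape, dtype=bool)
    zflat = wassr.z.reshape(-1, offs.size)
    vflat = values.reshape(-1)
    mflat = valid.reshape(-1)
    for i, spec in enumerate(zflat):
        if not np.all(np.isfinite(spec)) or np.ptp(spec) < 1e-6:
            continue
        cs = CubicSpline(offs[order], spec[order])
        dense = cs(fine)
        vflat[i] = fine[int(np.argmin(dense))]
        mflat[i] = True
    return B0Map(values, valid)


def normalize_and_correct(
    raw: np.ndarray,
    reference: np.ndarray,
    offsets: Sequence[float],
    b0: B0Map,
    geometry: CESTGeometry | None = None,
    b0_flag_ppm: float = 0.5,
) -> ZSpectrumStack:
    """Normalize a raw saturation stack by the reference image and correct
    each voxel's offset axis for the local B0 shift.

    The measured samples are treated as lying at effective offsets
    (nominal - B0) and re-interpolated (cubic spline) back onto the nominal
    grid; offsets falling outside the sampled range keep the edge value.
    Voxels with |B0| > ``b0_flag_ppm`` are flagged as unreliable.
    """
    offsets = np.asarray(offsets, dtype=float)
    raw = np.asarray(raw, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if raw.shape[-1] != offsets.size:
        raise ValueError("offset axis does not match offsets list")
    order = np.argsort(offsets)
    z = np.zeros_like(raw)
    ok = reference > 0
    np.divide(raw, reference[..., None], out=z, where=ok[..., None])

    flags = np.zeros(raw.shape[:-1], dtype=np.uint8)
    flags[~ok] |= 1  # zero reference
    flags[b0.valid_mask & (np.abs(b0.values) > b0_flag_ppm)] |= 2

    zc = z.copy()
    idx = np.argwhere(ok & b0.valid_mask & (b0.values != 0.0))
    for ijk in idx:
        t = tuple(ijk)
        shift = b0.values[t]
        eff = offsets[order] - shift
        cs = CubicSpline(eff, z[t][order])
        zc[t] = cs(np.clip(offsets, eff.min(), eff.max()))
    zc = np.clip(zc, 0.0, None)
    return ZSpectrumStack(
        zc, offsets, reference, geometry or CESTGeometry(), flags
    )


# ---------------------------------------------------------------------------
# five-pool model evaluation and fitting
# ---------------------------------------------------------------------------


def _bounds_vec(pools: Sequence[str]):
    lo, hi, x0 = [], [], []
    for pool in pools:
        keys = (
            ("amplitude", "t2_us", "center")
            if pool == "mt"
            else ("amplitude", "width", "center")
        )
        for k in keys:
            b = POOL_BOUNDS[pool][k]
            lo.append(b[0])
            hi.append(b[1])
            x0.append(b[2])
    return np.array(lo), np.array(hi), np.array(x0)


def _params_from_vec(vec: np.ndarray, pools: Sequence[str], base: PoolParameterSet):
    updates = {}
    for i, pool in enumerate(pools):
        updates[pool] = tuple(vec[3 * i : 3 * i + 3])
    return replace(base, **updates)


def evaluate_zspectrum(
    params: PoolParameterSet, offsets, larmor_mhz: float
) -> np.ndarray:
    """Model Z-spectrum 1 - sum(Lorentzians) - super-Lorentzian."""
    return params.zspectrum(np.asarray(offsets, dtype=float), larmor_mhz)


@dataclass
class PoolFitResult:
    """Voxelwise five-pool fit output.

    ``params`` maps pool name -> array of shape spatial + (3,); ``z_corr``
    is the full model curve on the fitting grid; ``residual_rms`` and
    ``converged`` are per-voxel diagnostics.
    """

    params: dict[str, np.ndarray]
    offsets: np.ndarray
    z_corr: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    larmor_mhz: float

    def pool_set(self, index: tuple) -> PoolParameterSet:
        return PoolParameterSet(
            **{pool: tuple(self.params[pool][index]) for pool in self.params}
        )

    def amplitude_map(self, pool: str) -> np.ndarray:
        return self.params[pool][..., 0]


def fit_mt_baseline(
    z: np.ndarray,
    offsets: np.ndarray,
    larmor_mhz: float,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Stage 1: water + MT fit against far-offset points (|dw| >= 8 ppm).

    Returns arrays ``water`` and ``mt`` of shape spatial + (3,) plus a
    ``converged`` flag array.
    """
    offsets = np.asarray(offsets, dtype=float)
    far = np.abs(offsets) > MT_EXCLUSION_PPM  # strictly outside the +/-8 ppm band
    if far.sum() < 6:
        raise ValueError(
            f"need at least 6 Z-spectrum points at |dw| > {MT_EXCLUSION_PPM} ppm"
        )
    pools = ("water", "mt")
    lo, hi, x0 = _bounds_vec(pools)
    # stage-1 model is water + MT only: solute pools are absent
    base = PoolParameterSet(
        noe=(0.0, 3.0, -3.5), amide=(0.0, 1.1, 3.5), amine=(0.0, 1.5, 2.0)
    )
    x_far = offsets[far]

    spatial = z.shape[:-1]
    water = np.zeros(spatial + (3,))
    mt = np.zeros(spatial + (3,))
    conv = np.zeros(spatial, dtype=bool)
    it = np.ndindex(spatial) if mask is None else map(tuple, np.argwhere(mask))
    for idx in it:
        y = z[idx][far]
        if not np.all(np.isfinite(y)):
            continue

        def resid(v):
            p = _params_from_vec(v, pools, base)
            return evaluate_zspectrum(p, x_far, larmor_mhz) - y

        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        water[idx] = sol.x[:3]
        mt[idx] = sol.x[3:]
        conv[idx] = sol.success
    return {"water": water, "mt": mt, "converged": conv}


def fit_five_pool(
    stack: ZSpectrumStack,
    mt_baseline: dict[str, np.ndarray],
    larmor_mhz: float,
    mask: np.ndarray | None = None,
) -> PoolFitResult:
    """Stage 2: joint five-pool refinement seeded by the MT baseline.

    All fifteen pool parameters are free within their bounds.  The fit is
    seeded from the stage-1 water/MT estimates; if the residual stays above
    the restart threshold (several times any realistic noise floor), the fit
    is repeated from the tabulated starting vector and from a variant with
    the NOE pool started at its canonical -3.5 ppm position, keeping the
    lowest-residual solution.  The multi-start guard matters at realistic
    noise levels: the objective has local minima in which the NOE pool
    swaps roles with the water or MT line, and a stage-1 MT amplitude
    estimated from ten far-offset points alone is itself too noisy to
    freeze outright.  Voxels that fail to converge are flagged and excluded
    from derived maps.
    """
    offsets = stack.offsets
    z = stack.z
    pools = ("water", "noe", "amide", "amine", "mt")
    lo, hi, x0_tab = _bounds_vec(pools)
    spatial = z.shape[:-1]
    out = {pool: np.zeros(spatial + (3,)) for pool in pools}
    z_corr = np.zeros(z.shape)
    rms = np.full(spatial, np.nan)
    conv = np.zeros(spatial, dtype=bool)
    fd_t2 = 1e-3  # us, forward-difference steps for the MT shape columns
    fd_c = 1e-4  # ppm

    it = np.ndindex(spatial) if mask is None else map(tuple, np.argwhere(mask))
    for idx in it:
        y = z[idx]
        if not np.all(np.isfinite(y)):
            continue

        def sl_shape(t2, c):
            return super_lorentzian_eval(offsets, 1.0, t2, c, larmor_mhz)

        def resid(v):
            model = 1.0 - v[12] * sl_shape(v[13], v[14])
            for i in range(4):
                a, w, c = v[3 * i : 3 * i + 3]
                model = model - lorentzian_eval(offsets, a, w, c)
            return model - y

        def jac(v):
            # Lorentzian and MT-amplitude columns analytic; MT shape
            # parameters by forward differences of the lineshape
            j = np.empty((offsets.size, 15))
            for i in range(4):
                a, w, c = v[3 * i : 3 * i + 3]
                d = offsets - c
                u = 1.0 + 4.0 * d * d / (w * w)
                j[:, 3 * i] = -1.0 / u
                j[:, 3 * i + 1] = -a * (8.0 * d * d / w**3) / u**2
                j[:, 3 * i + 2] = -a * (8.0 * d / (w * w)) / u**2
            g0 = sl_shape(v[13], v[14])
            j[:, 12] = -g0
            t2_step = fd_t2 if v[13] + fd_t2 <= hi[13] else -fd_t2
            c_step = fd_c if v[14] + fd_c <= hi[14] else -fd_c
            j[:, 13] = -v[12] * (sl_shape(v[13] + t2_step, v[14]) - g0) / t2_step
            j[:, 14] = -v[12] * (sl_shape(v[13], v[14] + c_step) - g0) / c_step
            return j

        def solve(x0):
            return least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                                 method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)

        mt0 = np.clip(mt_baseline["mt"][idx], lo[12:], hi[12:])
        x_a = x0_tab.copy()
        x_a[:2] = np.clip(mt_baseline["water"][idx][:2], lo[:2], hi[:2])
        x_a[12:] = mt0
        sol = solve(x_a)
        if np.sqrt(np.mean(sol.fun**2)) > _RESTART_RMS:
            x_b = x0_tab.copy()
            x_b[4:6] = (3.0, -3.5)  # NOE at its canonical position
            x_b[12:] = mt0
            for x0 in (x_b, x0_tab):
                alt = solve(x0)
                if np.sum(alt.fun**2) < np.sum(sol.fun**2):
                    sol = alt
        for i, pool in enumerate(pools):
            out[pool][idx] = sol.x[3 * i : 3 * i + 3]
        fitted = _params_from_vec(sol.x, pools, PoolParameterSet())
        z_corr[idx] = evaluate_zspectrum(fitted, offsets, larmor_mhz)
        rms[idx] = np.sqrt(np.mean((z_corr[idx] - y) ** 2))
        conv[idx] = sol.success
    return PoolFitResult(out, offsets, z_corr, rms, conv, larmor_mhz)


class FivePoolModel:
    """Model-object interface to the two-stage five-pool Z-spectrum fit.

    Parameters
    ----------
    stack : ZSpectrumStack
        Normalized, B0-corrected spectra.
    larmor_mhz : float
        Larmor frequency for the ppm -> rad/s conversion of the MT line.
    mask : ndarray of bool, optional
        Voxels to fit (default: all voxels with finite spectra).
    """

    def __init__(self, stack: ZSpectrumStack, larmor_mhz: float, mask=None):
        self.stack = stack
        self.larmor_mhz = larmor_mhz
        self.mask = mask

    def fit(self) -> PoolFitResult:
        stage1 = fit_mt_baseline(
            self.stack.z, self.stack.offsets, self.larmor_mhz, self.mask
        )
        return fit_five_pool(self.stack, stage1, self.larmor_mhz, self.mask)


def compute_arex(
    fit: PoolFitResult,
    qt1: QuantMap,
    pool: str,
    eval_offset: float | None = None,
    mask: np.ndarray | None = None,
) -> QuantMap:
    """AREX (apparent exchange-dependent relaxation) map for one pool, 1/s.

    AREX(dw) = (1/Z_corr(dw) - 1/Z_ref(dw)) * (1/T1), where Z_ref is the
    model spectrum with the named pool's amplitude set to zero (the
    saturation effect without the pool of interest) and T1 is in seconds.
    By default dw is the voxel's fitted pool center; pass ``eval_offset`` to
    evaluate at a fixed nominal offset instead.
    """
    if pool not in ("noe", "amide", "amine", "mt"):
        raise ValueError(f"unknown pool {pool!r}")
    qt1.require_units("ms", "compute_arex")
    spatial = fit.residual_rms.shape
    if qt1.values.shape != spatial:
        raise ValueError("qT1 map must be resampled to the CEST grid first")
    values = np.zeros(spatial)
    valid = np.zeros(spatial, dtype=bool)
    it = np.ndindex(spatial) if mask is None else map(tuple, np.argwhere(mask))
    for idx in it:
        if not fit.converged[idx]:
            continue
        t1_ms = qt1.values[idx]
        if qt1.valid_mask is not None and not qt1.valid_mask[idx]:
            continue
        if not np.isfinite(t1_ms) or t1_ms <= 0:
            continue
        p = fit.pool_set(idx)
        dw = float(getattr(p, pool)[2]) if eval_offset is None else float(eval_offset)
        z_corr = evaluate_zspectrum(p, dw, fit.larmor_mhz)
        _, b, c = getattr(p, pool)
        p_ref = replace(p, **{pool: (0.0, b, c)})
        z_ref = evaluate_zspectrum(p_ref, dw, fit.larmor_mhz)
        if z_corr <= 0 or z_ref <= 0:
            continue
        t1_s = t1_ms / 1000.0
        values[idx] = (1.0 / z_corr - 1.0 / z_ref) / t1_s
        valid[idx] = True
    return QuantMap(
        values, "1/s", {"stage": "compute_arex", "pool": pool}, valid
    )


def resample_to_cest(
    map3d: QuantMap,
    geometry: CESTGeometry,
    source_slice_thickness_mm: float = 0.25,
    occupancy_threshold: float = 0.5,
    is_mask: bool = False,
) -> QuantMap:
    """Downsample a 3-D map onto the multislice CEST grid.

    In-plane dimensions are kept (linear interpolation is the identity when
    grids match); through-plane, each CEST slice value is the box average of
    the source map over the slice's physical span, excluding the slice gaps.
    Masks are resampled the same way and re-binarized at the occupancy
    threshold.
    """
    vals = np.asarray(map3d.values, dtype=float)
    nz = vals.shape[2]
    src_edges = source_slice_thickness_mm * np.arange(nz + 1)
    out = np.zeros(vals.shape[:2] + (geometry.n_slices,))
    half = geometry.slice_thickness_mm / 2.0
    for j, zc in enumerate(geometry.slice_centers_mm):
        lo, hi = zc - half, zc + half
        if lo < src_edges[0] - 1e-9 or hi > src_edges[-1] + 1e-9:
            raise ValueError("CEST slab extends outside the source volume")
        overlap = np.clip(
            np.minimum(hi, src_edges[1:]) - np.maximum(lo, src_edges[:-1]), 0.0, None
        )
        w = overlap / overlap.sum()
        out[:, :, j] = np.tensordot(vals, w, axes=([2], [0]))
    if is_mask:
        out = out > occupancy_threshold
        return QuantMap(out.astype(float), map3d.units, {"stage": "resample_to_cest"})
    return QuantMap(
        out, map3d.units, {**map3d.provenance, "stage": "resample_to_cest"}
    )
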