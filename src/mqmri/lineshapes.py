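"""Saturation lineshapes for multi-pool Z-spectrum modelling.

The Z-spectrum model is phenomenological: the normalized water signal is

    Z(dw) = 1 - sum_i L_i(dw) - SL(dw)

where each exchanging/dipolar pool i (direct water saturation, amide at
+3.5 ppm, amine at +2.0 ppm, relayed NOE at -3.5 ppm) contributes a
Lorentzian

    L(dw; A, sigma, c) = A / (1 + 4 (dw - c)^2 / sigma^2)

with amplitude A (peak saturation fraction), FWHM sigma (ppm) and center c
(ppm), and the semisolid magnetization-transfer (MT) pool contributes a
super-Lorentzian absorption line parameterized by its transverse relaxation
time T2MT (microseconds).

The super-Lorentzian integrand diverges at the line center, so the inner
region (|dw - c| < 8 ppm) is bridged by a cubic spline through analytic
anchor points computed by quadrature at +/-{8, 10, 12, 16, 25, 50, 100, 200}
ppm from the center.  The lineshape is normalized by its bridged center
value so that the MT amplitude, like the Lorentzian amplitudes, is the peak
saturation fraction (dimensionless, bounded by 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "POOL_BOUNDS",
    "LORENTZIAN_POOLS",
    "SL_ANCHOR_PPM",
    "PoolParameterSet",
    "lorentzian_eval",
    "super_lorentzian_raw",
    "super_lorentzian_eval",
]

# Fit bounds and starting values per pool: {param: (lower, upper, start)}.
# Lorentzian pools carry (amplitude, width sigma in ppm FWHM, center ppm);
# the MT pool carries (amplitude, T2MT in microseconds, center ppm).
POOL_BOUNDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "water": {
        "amplitude": (0.02, 1.0, 0.9),
        "width": (0.3, 10.0, 1.4),
        "center": (-1.0, 1.0, 0.0),
    },
    "noe": {
        "amplitude": (0.0, 0.6, 0.02),
        "width": (0.5, 10.0, 3.0),
        "center": (-4.0, 0.0, -2.0),
    },
    "mt": {
        "amplitude": (0.0, 1.0, 0.1),
        "t2_us": (1.0, 50.0, 15.0),
        "center": (-4.0, 4.0, -2.0),
    },
    "amide": {
        "amplitude": (0.0, 2.0, 0.025),
        "width": (0.4, 4.0, 0.5),
        "center": (3.0, 4.0, 3.5),
    },
    "amine": {
        "amplitude": (0.0, 0.2, 0.01),
        "width": (0.5, 5.0, 1.5),
        "center": (1.75, 2.25, 2.0),
    },
}

LORENTZIAN_POOLS = ("water", "noe", "amide", "amine")

#: anchor offsets (ppm from the MT center) for the inner-region spline bridge
SL_ANCHOR_PPM = np.array([8.0, 10.0, 12.0, 16.0, 25.0, 50.0, 100.0, 200.0])

#: width of the spline-bridged inner region, ppm from the MT center
SL_INNER_PPM = 8.0

_MAGIC_U = 1.0 / np.sqrt(3.0)

def _graded_panels(a: float, b: float, levels: int = 26, order: int = 10):
    """Composite Gauss-Legendre nodes on (a, b), geometrically graded toward
    both endpoints (the integrand has boundary layers at the magic angle and
    at u = 1 whose width depends on the offset).
    """
    gx, gw = np.polynomial.legendre.leggauss(order)
    gx = 0.5 * (gx + 1.0)
    gw = 0.5 * gw
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    cuts = [a] + [a + half * 2.0 ** (-k) for k in range(levels, 0, -1)]
    cuts += [mid] + [b - half * 2.0 ** (-k) for k in range(1, levels + 1)] + [b]
    cuts = np.asarray(cuts)
    lo, hi = cuts[:-1], cuts[1:]
    nodes = (lo[:, None] + (hi - lo)[:, None] * gx[None, :]).ravel()
    weights = ((hi - lo)[:, None] * gw[None, :]).ravel()
    return nodes, weights


_panels = [_graded_panels(0.0, _MAGIC_U), _graded_panels(_MAGIC_U, 1.0)]


def lorentzian_eval(offset, amplitude, width, center):
    """Lorentzian saturation fraction; ``width`` is the FWHM in ppm."""
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("Lorentzian width must be positive")
    d = (np.asarray(offset, dtype=float) - center) / width
    return amplitude / (1.0 + 4.0 * d * d)


def _sl_integrand(u, omega_t2):
    """Super-Lorentzian integrand after the substitution u = cos(theta).

    ``omega_t2`` is the dimensionless product (angular offset from the MT
    center) x T2MT.  The integrand has an essential zero at the magic angle
    u = 1/sqrt(3) for any nonzero offset; it is defined as 0 there.
    """
    q = 3.0 * u * u - 1.0
    out = np.zeros(np.broadcast_shapes(u.shape, np.shape(omega_t2)))
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        val = np.sqrt(2.0 / np.pi) / np.abs(q) * np.exp(-2.0 * (omega_t2 / q) ** 2)
    np.copyto(out, val, where=np.abs(q) > 1e-300)
    return out


def super_lorentzian_raw(delta_ppm, t2_us, larmor_mhz):
    """Quadrature evaluation of the super-Lorentzian absorption integral.

    Parameters
    ----------
    delta_ppm : array-like
        Offset from the MT line center, ppm.  Must satisfy |delta| > 0; the
        integral diverges logarithmically at the exact center.
    t2_us : float
        T2 of the semisolid pool, microseconds.
    larmor_mhz : float
        Larmor frequency in MHz (converts ppm to rad/s).

    Returns
    -------
    ndarray
        Integral of the standard super-Lorentzian integrand over
        theta in [0, pi/2] (substituted to u = cos theta and split at the
        magic angle), in units of T2 (seconds).  Multiply by an amplitude to
        obtain a saturation fraction; see :func:`super_lorentzian_eval` for
        the normalized form.
    """
    delta_ppm = np.atleast_1d(np.asarray(delta_ppm, dtype=float))
    if np.any(delta_ppm == 0.0):
        raise ValueError("super-Lorentzian integral diverges at the line center")
    t2_s = float(t2_us) * 1e-6
    omega = 2.0 * np.pi * larmor_mhz * delta_ppm  # rad/s (MHz * ppm -> Hz)
    wt2 = (omega * t2_s)[..., None]  # broadcast over quadrature nodes

    total = np.zeros(delta_ppm.shape)
    for u, w in _panels:
        total += _sl_integrand(u[None, :], wt2).dot(w)
    return t2_s * total


@lru_cache(maxsize=256)
def _sl_bridge(t2_us: float, larmor_mhz: float):
    """Cubic spline through the symmetric anchor values, in delta-ppm space.

    Cached: the generator and the stage-2 fit evaluate the same (T2MT,
    Larmor) pair millions of times.
    """
    anchors = np.concatenate([-SL_ANCHOR_PPM[::-1], SL_ANCHOR_PPM])
    vals = super_lorentzian_raw(anchors, t2_us, larmor_mhz)
    return CubicSpline(anchors, vals)


def super_lorentzian_eval(offset, amplitude, t2_us, center, larmor_mhz):
    """Normalized super-Lorentzian saturation fraction.

    For |offset - center| >= 8 ppm the quadrature value is used; inside that
    band a cubic spline through the anchor points bridges the singular
    region.  The result is scaled so the value at the center equals
    ``amplitude`` (peak saturation fraction).
    """
    lo, hi, _ = POOL_BOUNDS["mt"]["t2_us"]
    if not (lo <= t2_us <= hi):
        raise ValueError(f"T2MT {t2_us} outside bounds [{lo}, {hi}] us")
    offset = np.asarray(offset, dtype=float)
    delta = np.atleast_1d(offset - center)
    spline = _sl_bridge(float(t2_us), float(larmor_mhz))
    peak = float(spline(0.0))
    out = np.empty(delta.shape)
    inner = np.abs(delta) < SL_INNER_PPM
    if np.any(inner):
        out[inner] = spline(delta[inner])
    if np.any(~inner):
        out[~inner] = super_lorentzian_raw(delta[~inner], t2_us, larmor_mhz)
    out = amplitude * out / peak
    return out.reshape(np.shape(offset)) if np.shape(offset) else float(out[0])


@dataclass(frozen=True)
class PoolParameterSet:
    """Five-pool Z-spectrum parameters for one tissue.

    Lorentzian pools are (amplitude, FWHM sigma in ppm, center in ppm);
    the MT pool is (amplitude, T2MT in microseconds, center in ppm).
    """

    water: tuple[float, float, float] = (0.85, 1.4, 0.0)
    noe: tuple[float, float, float] = (0.05, 3.0, -3.5)
    amide: tuple[float, float, float] = (0.03, 1.1, 3.5)
    amine: tuple[float, float, float] = (0.03, 1.5, 2.0)
    mt: tuple[float, float, float] = (0.08, 15.0, -2.0)

    def validate(self) -> None:
        """Check every parameter against the fit bounds table and the
        physical requirement that total saturation stays below 1."""
        for pool in LORENTZIAN_POOLS:
            a, w, c = getattr(self, pool)
            b = POOL_BOUNDS[pool]
            for val, key in ((a, "amplitude"), (w, "width"), (c, "center")):
                lo, hi, _ = b[key]
                if not (lo <= val <= hi):
                    raise ValueError(f"{pool} {key}={val} outside bounds [{lo}, {hi}]")
        a, t2, c = self.mt
        for val, key in ((a, "amplitude"), (t2, "t2_us"), (c, "center")):
            lo, hi, _ = POOL_BOUNDS["mt"][key]
            if not (lo <= val <= hi):
                raise ValueError(f"mt {key}={val} outside bounds [{lo}, {hi}]")
        grid = np.linspace(-10.0, 10.0, 401)
        if np.max(self.saturation(grid, larmor_mhz=400.0)) >= 1.0:
            raise ValueError("total saturation reaches 1; Z would go negative")

    def saturation(self, offsets_ppm, larmor_mhz: float) -> np.ndarray:
        """Total saturation fraction sum(L_i) + SL at the given offsets."""
        offsets_ppm = np.asarray(offsets_ppm, dtype=float)
        sat = np.zeros(offsets_ppm.shape)
        for pool in LORENTZIAN_POOLS:
            a, w, c = getattr(self, pool)
            sat += lorentzian_eval(offsets_ppm, a, w, c)
        a, t2, c = self.mt
        if a > 0:
            sat += super_lorentzian_eval(offsets_ppm, a, t2, c, larmor_mhz)
        return sat

    def zspectrum(self, offsets_ppm, larmor_mhz: float) -> np.ndarray:
        """Model Z-spectrum 1 - sum(L) - SL (not clipped)."""
        return 1.0 - self.saturation(offsets_ppm, larmor_mhz)
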