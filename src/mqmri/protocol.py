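"""Acquisition protocol description for the 9.4 T mouse multiecho-GRE / CEST study.

The protocol object is deliberately dumb: it records the timing, flip angles,
and saturation-offset grids that every downstream stage (simulation,
relaxometry, QSM, CEST fitting) must agree on, and performs the unit
conversions (ppm <-> Hz <-> rad/s) exactly once so there is a single source
of truth for the Larmor frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: gyromagnetic ratio of the proton, MHz per tesla
GAMMA_MHZ_PER_T = 42.577478518


def _default_echo_times() -> list[float]:
    # TE_i = 2.177 + 2.47 * (i - 1) ms, i = 1..8
    return [2.177 + 2.47 * i for i in range(8)]


def _default_cest_offsets() -> list[float]:
    # uniform -8..+8 ppm grid at 0.25 ppm
    return list(np.round(np.arange(-8.0, 8.0 + 1e-9, 0.25), 6))


def _default_far_offsets() -> list[float]:
    return [-200.0, -100.0, -50.0, -25.0, -16.0, 16.0, 25.0, 50.0, 100.0, 200.0]


def _default_wassr_offsets() -> list[float]:
    return list(np.round(np.arange(-1.0, 1.0 + 1e-9, 0.05), 6))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, flip-angle and saturation-offset metadata shared by all stages.

    Parameters
    ----------
    echo_times : sequence of float
        Gradient-echo times in ms, strictly increasing.
    tr : float
        Repetition time in ms.
    flip_angles : sequence of float
        Excitation flip angles in degrees (two angles for DESPOT1).
    field_strength : float
        Static field in tesla; the Larmor frequency is derived from it.
    cest_offsets, far_offsets : sequence of float
        Saturation offsets in ppm for the inner Z-spectrum grid and the
        far-offset points used for the MT baseline.
    reference_offset : float
        Offset (ppm) of the unsaturated reference acquisition; excluded from
        every fitting grid.
    wassr_offsets : sequence of float
        Offsets (ppm) of the WASSR B0-mapping sweep.
    sat_power_ut, sat_duration_ms : float / tuple
        Saturation amplitude (uT) and durations (ms); recorded metadata only,
        the lineshape model does not consume them.
    """

    echo_times: Sequence[float] = field(default_factory=_default_echo_times)
    tr: float = 33.57
    flip_angles: Sequence[float] = (15.0, 40.0)
    field_strength: float = 9.4
    cest_offsets: Sequence[float] = field(default_factory=_default_cest_offsets)
    far_offsets: Sequence[float] = field(default_factory=_default_far_offsets)
    reference_offset: float = -300.0
    wassr_offsets: Sequence[float] = field(default_factory=_default_wassr_offsets)
    sat_power_ut: float = 1.0
    sat_duration_ms: tuple[float, float] = (5000.0, 1000.0)

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.tr <= te.max():
            raise ValueError("TR must exceed the longest echo time")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        for name in ("cest_offsets", "far_offsets", "wassr_offsets"):
            offs = np.asarray(getattr(self, name), dtype=float)
            if offs.size != np.unique(offs).size:
                raise ValueError(f"{name} contains duplicate offsets")
        if self.reference_offset in set(self.cest_offsets) | set(self.far_offsets):
            raise ValueError("reference offset must not appear in a fitting grid")

    # ---- derived quantities -------------------------------------------------

    @property
    def larmor_mhz(self) -> float:
        """Proton Larmor frequency in MHz (≈400.2 MHz at 9.4 T)."""
        return GAMMA_MHZ_PER_T * self.field_strength

    @property
    def hz_per_ppm(self) -> float:
        """Frequency per ppm of chemical shift, in Hz."""
        return self.larmor_mhz  # 1 ppm = larmor(MHz) Hz

    def ppm_to_rad_per_s(self, ppm):
        return 2.0 * np.pi * self.hz_per_ppm * np.asarray(ppm, dtype=float)

    @property
    def delta_te(self) -> float:
        """Echo spacing in ms; raises if echoes are not equally spaced."""
        d = np.diff(np.asarray(self.echo_times, dtype=float))
        if d.size and not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
            raise ValueError("echo times are not equally spaced")
        return float(d[0]) if d.size else 0.0

    @property
    def zspec_offsets(self) -> np.ndarray:
        """Full CEST fitting grid (inner grid plus far offsets), sorted, ppm."""
        return np.sort(
            np.concatenate(
                [np.asarray(self.cest_offsets, float), np.asarray(self.far_offsets, float)]
            )
        )
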