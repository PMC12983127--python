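"""Digital brain phantom: labeled tissue grid with full MR ground truth.

The phantom is a deliberately simple geometric stand-in for a mouse brain —
an ellipsoidal "brain" containing four ellipsoidal gray/white-matter regions
of interest (hippocampus, corpus callosum, thalamus, striatum) and a central
CSF compartment.  Each tissue class carries everything the forward models
need: proton density M0, longitudinal relaxation time T1 (ms), apparent
transverse relaxation rate R2* (1/s), magnetic susceptibility chi (ppm), and
a five-pool CEST parameter set.  The geometry is not anatomical; every
downstream algorithm is geometry-agnostic, and small grids keep the whole
pipeline testable.

Genotype differences (wild-type WT vs the amyloid-bearing ARTE10 line) are
programmed through an effect table expressed in within-group standard
deviation units per (ROI, metric), mirroring the directions reported for
this animal model: higher hippocampal susceptibility and R2*, higher
thalamic qT1, and reduced NOE/amide AREX.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .lineshapes import POOL_BOUNDS, PoolParameterSet

ROI_NAMES = ("hippocampus", "corpus_callosum", "thalamus", "striatum")
METRICS = ("r2s", "chi", "qt1", "arex_amide", "arex_noe")
GENOTYPES = ("WT", "ARTE10")


@dataclass(frozen=True)
class TissueClass:
    """Per-tissue MR ground truth."""

    label: int
    name: str
    m0: float
    t1: float  # ms
    r2s: float  # 1/s
    chi: float  # ppm
    pools: PoolParameterSet = field(default_factory=PoolParameterSet)

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.r2s < 0 or self.m0 < 0:
            raise ValueError("r2s and m0 must be non-negative")


def _default_classes() -> dict[str, TissueClass]:
    """WT tissue table.  Values are plausible for mouse brain at 9.4 T."""
    P = PoolParameterSet
    return {
        "brain": TissueClass(1, "brain", 1000.0, 1800.0, 28.0, 0.000,
                             P((0.85, 1.4, 0.0), (0.050, 3.0, -3.5),
                               (0.030, 1.1, 3.5), (0.030, 1.5, 2.0), (0.08, 15.0, -2.0))),
        "hippocampus": TissueClass(2, "hippocampus", 1000.0, 1850.0, 30.0, 0.010,
                                   P((0.85, 1.4, 0.0), (0.050, 3.0, -3.5),
                                     (0.030, 1.1, 3.5), (0.030, 1.5, 2.0), (0.08, 15.0, -2.0))),
        "corpus_callosum": TissueClass(3, "corpus_callosum", 950.0, 1700.0, 34.0, -0.015,
                                       P((0.85, 1.6, 0.0), (0.070, 3.0, -3.5),
                                         (0.028, 1.1, 3.5), (0.025, 1.5, 2.0), (0.10, 15.0, -2.0))),
        "thalamus": TissueClass(4, "thalamus", 1000.0, 1750.0, 32.0, 0.005,
                                P((0.85, 1.4, 0.0), (0.060, 3.0, -3.5),
                                  (0.030, 1.1, 3.5), (0.030, 1.5, 2.0), (0.09, 15.0, -2.0))),
        "striatum": TissueClass(5, "striatum", 1000.0, 1800.0, 30.0, 0.008,
                                P((0.85, 1.4, 0.0), (0.055, 3.0, -3.5),
                                  (0.030, 1.1, 3.5), (0.030, 1.5, 2.0), (0.09, 15.0, -2.0))),
        "csf": TissueClass(6, "csf", 1000.0, 3500.0, 6.0, 0.000,
                           P((0.92, 1.0, 0.0), (0.002, 3.0, -3.5),
                             (0.002, 1.1, 3.5), (0.002, 1.5, 2.0), (0.002, 15.0, 0.0))),
    }


# Within-group SD of a per-animal ROI summary for each metric.  Relative
# entries are coefficients of variation; chi uses an absolute SD because its
# mean is near zero.  These define the "SD units" of the effect table.
METRIC_SD = {
    "r2s": ("relative", 0.02),
    "qt1": ("relative", 0.02),
    "chi": ("absolute", 0.0015),  # ppm
    "arex_amide": ("relative", 0.04),  # SD of the amide pool amplitude
    "arex_noe": ("relative", 0.04),  # SD of the NOE pool amplitude
}


def default_effect_table() -> dict[tuple[str, str], float]:
    """Genotype shifts (ARTE10 - WT) in within-group SD units per (roi, metric),
    following the reported effect-size pattern for this mouse line."""
    g = {
        ("hippocampus", "r2s"): 1.22, ("corpus_callosum", "r2s"): 0.99,
        ("thalamus", "r2s"): 1.20, ("striatum", "r2s"): 1.22,
        ("hippocampus", "chi"): 1.99, ("corpus_callosum", "chi"): 0.41,
        ("thalamus", "chi"): -0.37, ("striatum", "chi"): 1.08,
        ("hippocampus", "qt1"): 0.73, ("corpus_callosum", "qt1"): 0.11,
        ("thalamus", "qt1"): 1.84, ("striatum", "qt1"): 0.20,
        ("hippocampus", "arex_amide"): -0.69, ("corpus_callosum", "arex_amide"): -0.20,
        ("thalamus", "arex_amide"): -1.34, ("striatum", "arex_amide"): -0.46,
        ("hippocampus", "arex_noe"): -1.81, ("corpus_callosum", "arex_noe"): -2.40,
        ("thalamus", "arex_noe"): -2.64, ("striatum", "arex_noe"): -1.10,
    }
    return g


def metric_sd(metric: str, mean: float) -> float:
    kind, v = METRIC_SD[metric]
    return v if kind == "absolute" else v * abs(mean)


@dataclass
class DigitalPhantom:
    """Labeled 3-D tissue grid plus everything needed to forward-simulate."""

    label_volume: np.ndarray
    class_table: dict[int, TissueClass]
    roi_masks: dict[str, np.ndarray]
    b0_offset: np.ndarray  # ppm
    genotype: str
    voxel_size_mm: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        labels = np.unique(self.label_volume)
        for lab in labels[labels > 0]:
            if int(lab) not in self.class_table:
                raise ValueError(f"label {lab} has no tissue class")
        if not np.all(np.isfinite(self.b0_offset)):
            raise ValueError("b0 offset field must be finite")
        csf = self.roi_masks.get("csf")
        if csf is not None:
            for name, m in self.roi_masks.items():
                if name != "csf" and np.any(m & csf):
                    raise ValueError(f"ROI {name} overlaps the CSF mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def parameter_map(self, attr: str) -> np.ndarray:
        """Scalar ground-truth volume for a TissueClass attribute."""
        out = np.zeros(self.shape, dtype=float)
        for lab, cls in self.class_table.items():
            out[self.label_volume == lab] = getattr(cls, attr)
        return out

    def class_for_roi(self, roi: str) -> TissueClass:
        for cls in self.class_table.values():
            if cls.name == roi:
                return cls
        raise KeyError(roi)


# (center, semi-axes) in fractional grid coordinates
_GEOMETRY = {
    "brain": ((0.50, 0.50, 0.50), (0.46, 0.46, 0.48)),
    "csf": ((0.50, 0.50, 0.50), (0.06, 0.09, 0.30)),
    "hippocampus": ((0.30, 0.50, 0.50), (0.10, 0.13, 0.30)),
    "corpus_callosum": ((0.50, 0.26, 0.50), (0.16, 0.06, 0.35)),
    "thalamus": ((0.68, 0.50, 0.50), (0.10, 0.10, 0.30)),
    "striatum": ((0.50, 0.74, 0.50), (0.12, 0.09, 0.30)),
}


def _ellipsoid(dims, center_frac, semi_frac, scale=1.0) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in dims], indexing="ij")
    q = np.zeros(dims)
    for g, n, c, s in zip(grids, dims, center_frac, semi_frac):
        q += ((g - c * (n - 1)) / max(s * n * scale, 0.5)) ** 2
    return q <= 1.0


def _smooth_b0_field(dims, rng: np.random.Generator, amp_ppm: float = 0.15) -> np.ndarray:
    """Smooth random B0 offset field (ppm): a few broad Gaussian blobs."""
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in dims], indexing="ij")
    f = np.zeros(dims)
    for _ in range(3):
        c = rng.uniform(-0.5, 0.5, size=3)
        w = rng.uniform(0.6, 1.2, size=3)
        a = rng.uniform(-1.0, 1.0)
        r2 = sum(((g - ci) / wi) ** 2 for g, ci, wi in zip(grids, c, w))
        f += a * np.exp(-r2)
    peak = np.max(np.abs(f))
    return amp_ppm * f / peak if peak > 0 else f


def _shifted_classes(
    classes: dict[str, TissueClass],
    genotype: str,
    effect_table: Mapping[tuple[str, str], float],
    sd_multiplier: float = 1.0,
) -> dict[str, TissueClass]:
    if genotype == "WT":
        return dict(classes)
    out = dict(classes)
    for (roi, metric), shift in effect_table.items():
        if roi not in out:
            raise KeyError(f"effect table references unknown ROI {roi!r}")
        if metric not in METRICS:
            raise KeyError(f"effect table references unknown metric {metric!r}")
        cls = out[roi]
        if metric in ("r2s", "chi"):
            base = getattr(cls, metric)
            delta = shift * metric_sd(metric, base) * sd_multiplier
            out[roi] = replace(cls, **{metric: base + delta})
        elif metric == "qt1":
            delta = shift * metric_sd(metric, cls.t1) * sd_multiplier
            out[roi] = replace(cls, t1=cls.t1 + delta)
        else:
            pool = "amide" if metric == "arex_amide" else "noe"
            a, w, c = getattr(cls.pools, pool)
            a2 = a + shift * metric_sd(metric, a) * sd_multiplier
            lo, hi, _ = POOL_BOUNDS[pool]["amplitude"]
            a2 = float(np.clip(a2, lo, hi))
            out[roi] = replace(cls, pools=replace(cls.pools, **{pool: (a2, w, c)}))
    return out


def build_phantom(
    dims: tuple[int, int, int] = (64, 64, 16),
    genotype: str = "WT",
    seed: int = 0,
    effect_table: Mapping[tuple[str, str], float] | None = None,
    jitter_geometry: bool = True,
    b0_amp_ppm: float = 0.15,
) -> DigitalPhantom:
    """Construct a deterministic labeled phantom.

    Parameters
    ----------
    dims : tuple of int
        Grid size; each axis must be at least 16 so all ROIs fit.
    genotype : {"WT", "ARTE10"}
        ARTE10 applies the effect-table mean shifts to the tissue classes.
    seed : int
        Drives the B0 field realization and the small per-build ROI size
        jitter (so ROI volumes vary between animals).
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 16 for d in dims):
        raise ValueError("dims must be 3-D with every axis >= 16 to place all ROIs")
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    rng = np.random.default_rng(seed)
    effect_table = default_effect_table() if effect_table is None else dict(effect_table)

    classes = _shifted_classes(_default_classes(), genotype, effect_table)
    for cls in classes.values():
        cls.pools.validate()

    labels = np.zeros(dims, dtype=np.int16)
    labels[_ellipsoid(dims, *_GEOMETRY["brain"])] = classes["brain"].label
    roi_masks: dict[str, np.ndarray] = {}
    for name in ("csf",) + ROI_NAMES:
        scale = float(rng.normal(1.0, 0.02)) if jitter_geometry else 1.0
        mask = _ellipsoid(dims, *_GEOMETRY[name], scale=np.clip(scale, 0.9, 1.1))
        mask &= labels == classes["brain"].label  # ROIs live inside the brain
        if not mask.any():
            raise ValueError(f"dims {dims} too small to place ROI {name!r}")
        labels[mask] = classes[name].label
        roi_masks[name] = mask

    class_table = {cls.label: cls for cls in classes.values()}
    b0 = _smooth_b0_field(dims, rng, amp_ppm=b0_amp_ppm)
    return DigitalPhantom(labels, class_table, roi_masks, b0, genotype)
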