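"""Forward simulation of all MR signals the pipeline consumes.

Signals are generated directly from the closed-form steady-state models the
analysis stages invert — SPGR magnitude with monoexponential T2* decay and
dipole-field phase for the multiecho GRE, and the five-pool lineshape model
for CEST/WASSR Z-spectra.  Time-domain saturation physics (Bloch-McConnell)
is deliberately not simulated: the generative model is exactly the model
the fitter assumes, which makes parameter recovery testable to numerical
precision.  Saturation power and duration are carried as protocol metadata
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cest import CESTGeometry, ZSpectrumStack
from .lineshapes import POOL_BOUNDS
from .phantom import (
    DigitalPhantom,
    GENOTYPES,
    METRICS,
    ROI_NAMES,
    TissueClass,
    build_phantom,
    default_effect_table,
    metric_sd,
    _default_classes,
    _GEOMETRY,
)
from .protocol import AcquisitionProtocol
from .qsm import dipole_field
from .relaxometry import MultiEchoGRE

__all__ = [
    "add_noise",
    "simulate_spgr_multiecho",
    "simulate_zspectrum_stack",
    "CohortSpec",
    "CohortBundle",
    "simulate_cohort",
    "derive_arex_truth",
]

#: WASSR direct-saturation line (low-power sweep): amplitude and FWHM (ppm)
WASSR_LINE = (0.8, 0.25)


def add_noise(volume: np.ndarray, sd: float, model: str = "gaussian", seed=None):
    """Add measurement noise to a simulated volume.

    ``gaussian`` adds i.i.d. noise (independently to real and imaginary
    parts if the input is complex); ``rician`` returns the magnitude of the
    complex-Gaussian-corrupted signal and therefore requires real input.
    ``sd = 0`` returns the input unchanged.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return volume
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        if np.iscomplexobj(volume):
            return volume + rng.normal(0, sd, volume.shape) + 1j * rng.normal(
                0, sd, volume.shape
            )
        return volume + rng.normal(0, sd, volume.shape)
    if model == "rician":
        if np.iscomplexobj(volume):
            raise ValueError(
                "rician noise is defined for magnitude output; input must be real"
            )
        return np.abs(
            volume + rng.normal(0, sd, volume.shape) + 1j * rng.normal(0, sd, volume.shape)
        )
    raise ValueError(f"unknown noise model {model!r}")


def spgr_signal(m0, t1_ms, r2s_per_s, te_ms, tr_ms, flip_deg):
    """Closed-form spoiled gradient-echo steady-state magnitude."""
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(flip_deg)
    return (
        m0
        * np.sin(a)
        * (1.0 - e1)
        / (1.0 - e1 * np.cos(a))
        * np.exp(-np.asarray(te_ms) * r2s_per_s / 1000.0)
    )


def simulate_spgr_multiecho(
    phantom: DigitalPhantom,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    seed=None,
    phi0: float = 0.3,
) -> dict[float, MultiEchoGRE]:
    """Simulate complex multiecho SPGR volumes for each protocol flip angle.

    Magnitude follows the SPGR steady state with monoexponential T2* decay;
    phase is 2*pi*f*TE + phi0 with f the forward dipole field of the
    phantom's susceptibility distribution (in Hz at the protocol's field
    strength).  Gaussian complex noise of ``noise_sd`` (signal units) is
    added per flip angle with independent substreams.
    """
    if protocol.tr <= 0:
        raise ValueError("TR must be positive")
    m0 = phantom.parameter_map("m0")
    t1 = phantom.parameter_map("t1")
    r2s = phantom.parameter_map("r2s")
    chi = phantom.parameter_map("chi")
    brain = phantom.brain_mask
    if np.any(t1[brain] <= 0):
        raise ValueError("T1 must be positive everywhere inside tissue")
    t1 = np.where(t1 <= 0, 1.0, t1)  # background placeholder, signal is 0 there

    field_hz = dipole_field(chi) * protocol.hz_per_ppm
    te = np.asarray(protocol.echo_times, dtype=float)
    out: dict[float, MultiEchoGRE] = {}
    root = np.random.default_rng(seed)
    for fa in protocol.flip_angles:
        mag = spgr_signal(
            m0[..., None], t1[..., None], r2s[..., None], te[None, None, None, :],
            protocol.tr, fa,
        )
        phase = 2.0 * np.pi * field_hz[..., None] * (te[None, None, None, :] * 1e-3) + phi0
        data = mag * np.exp(1j * phase)
        data = add_noise(data, noise_sd, "gaussian", root.integers(2**31))
        out[fa] = MultiEchoGRE(data, te, fa, protocol.tr)
    return out


def _cest_slice_indices(
    phantom: DigitalPhantom, geometry: CESTGeometry
) -> np.ndarray:
    """Source z-index of each CEST slice (slices align with source slices)."""
    dz = phantom.voxel_size_mm[2]
    idx = np.round(geometry.slice_centers_mm / dz - 0.5).astype(int)
    if idx.min() < 0 or idx.max() >= phantom.shape[2]:
        raise ValueError("CEST slab extends outside the phantom volume")
    return idx


def simulate_zspectrum_stack(
    phantom: DigitalPhantom,
    protocol: AcquisitionProtocol,
    mode: str = "cest",
    noise_sd: float = 0.0,
    seed=None,
    geometry: CESTGeometry | None = None,
) -> ZSpectrumStack:
    """Simulate a normalized multislice saturation stack.

    In ``cest`` mode each voxel's spectrum is the five-pool model of its
    tissue class evaluated at (dw - b0), clipped to [0, 1]; in ``wassr``
    mode a single narrow direct-saturation Lorentzian centered at the local
    B0 offset is used.  The unsaturated reference image (acquired at the
    protocol's -300 ppm reference offset, far outside every line) equals
    the proton-density image.  Gaussian noise of ``noise_sd`` (in units of
    the reference signal) corrupts the raw stack before normalization.
    """
    if mode not in ("cest", "wassr"):
        raise ValueError("mode must be 'cest' or 'wassr'")
    geometry = geometry or CESTGeometry()
    if mode == "cest":
        offsets = protocol.zspec_offsets
    else:
        offsets = np.sort(np.asarray(protocol.wassr_offsets, dtype=float))
    if offsets.size == 0:
        raise ValueError(f"protocol has no offsets for mode {mode!r}")

    zidx = _cest_slice_indices(phantom, geometry)
    labels = phantom.label_volume[:, :, zidx]
    b0 = phantom.b0_offset[:, :, zidx]
    m0 = phantom.parameter_map("m0")[:, :, zidx]

    z = np.zeros(labels.shape + (offsets.size,))
    for lab, cls in phantom.class_table.items():
        sel = labels == lab
        if not sel.any():
            continue
        delta = offsets[None, :] - b0[sel][:, None]
        if mode == "cest":
            cls.pools.validate()
            zv = cls.pools.zspectrum(delta, protocol.larmor_mhz)
        else:
            a, w = WASSR_LINE
            zv = 1.0 - a / (1.0 + 4.0 * (delta / w) ** 2)
        z[sel] = np.clip(zv, 0.0, 1.0)

    raw = m0[..., None] * z
    raw = add_noise(raw, noise_sd, "gaussian", seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_obs = np.where(m0[..., None] > 0, raw / np.where(m0 == 0, 1, m0)[..., None], 0.0)
    return ZSpectrumStack(np.clip(z_obs, 0.0, 1.2), offsets, m0, geometry)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-genotype synthetic cohort.

    ``effect_table`` maps (roi, metric) to the genotype shift in within-group
    SD units; ``noise_sd`` carries per-signal-type acquisition noise levels
    used when images are rendered.
    """

    n_per_genotype: int = 6
    effect_table: Mapping[tuple[str, str], float] | None = None
    noise_sd: Mapping[str, float] = dc_field(
        default_factory=lambda: {"gre": 2.0, "zspec": 5.0}
    )
    seed: int = 0
    dims: tuple[int, int, int] = (64, 64, 16)

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ValueError("need at least 2 animals per genotype")
        table = self.effect_table
        if table is not None:
            for (roi, metric), shift in table.items():
                if roi not in ROI_NAMES:
                    raise ValueError(f"effect table references unknown ROI {roi!r}")
                if metric not in METRICS:
                    raise ValueError(f"effect table references unknown metric {metric!r}")
                if not np.isfinite(shift):
                    raise ValueError("effect shifts must be finite")


@dataclass
class AnimalRecord:
    animal_id: str
    genotype: str
    seed: int
    classes: dict[str, TissueClass]
    phantom: DigitalPhantom | None = None


@dataclass
class CohortBundle:
    spec: CohortSpec
    protocol: AcquisitionProtocol
    animals: list[AnimalRecord]
    truth: pd.DataFrame


def derive_arex_truth(cls: TissueClass, pool: str, larmor_mhz: float) -> float:
    """Ground-truth AREX (1/s) implied by a tissue class's pool parameters."""
    p = cls.pools
    dw = float(getattr(p, pool)[2])
    z_corr = float(p.zspectrum(np.array(dw), larmor_mhz))
    _, b, c = getattr(p, pool)
    z_ref = float(replace(p, **{pool: (0.0, b, c)}).zspectrum(np.array(dw), larmor_mhz))
    return (1.0 / z_corr - 1.0 / z_ref) / (cls.t1 / 1000.0)


_ANIMAL_JITTER_CV = 0.02  # between-animal CV on m0/T1/R2* of non-ROI tissues


def _sample_animal_classes(
    rng: np.random.Generator,
    genotype: str,
    effect_table: Mapping[tuple[str, str], float],
) -> dict[str, TissueClass]:
    """Draw one animal's tissue parameters.

    Each ROI metric is mean + genotype shift + shared animal effect +
    ROI-level noise, with the animal and ROI components each carrying half
    the within-group variance (the shared component is what the mixed model
    later absorbs as the random animal intercept).
    """
    classes = _default_classes()
    animal_eff = {m: rng.normal() for m in METRICS}
    out: dict[str, TissueClass] = {}
    for name, cls in classes.items():
        if name in ROI_NAMES:
            vals = {}
            pools = cls.pools
            for metric in METRICS:
                if metric == "r2s":
                    base = cls.r2s
                elif metric == "chi":
                    base = cls.chi
                elif metric == "qt1":
                    base = cls.t1
                elif metric == "arex_amide":
                    base = pools.amide[0]
                else:
                    base = pools.noe[0]
                sd_w = metric_sd(metric, base)
                shift = effect_table.get((name, metric), 0.0) if genotype == "ARTE10" else 0.0
                val = (
                    base
                    + shift * sd_w
                    + animal_eff[metric] * sd_w / np.sqrt(2.0)
                    + rng.normal() * sd_w / np.sqrt(2.0)
                )
                vals[metric] = val
            a_lo, a_hi, _ = POOL_BOUNDS["amide"]["amplitude"]
            n_lo, n_hi, _ = POOL_BOUNDS["noe"]["amplitude"]
            pools = replace(
                pools,
                amide=(float(np.clip(vals["arex_amide"], a_lo + 1e-4, a_hi - 1e-4)),)
                + pools.amide[1:],
                noe=(float(np.clip(vals["arex_noe"], n_lo + 1e-4, n_hi - 1e-4)),)
                + pools.noe[1:],
            )
            out[name] = replace(
                cls,
                r2s=max(vals["r2s"], 0.0),
                chi=vals["chi"],
                t1=max(vals["qt1"], 1.0),
                pools=pools,
            )
        else:
            out[name] = replace(
                cls,
                m0=cls.m0 * rng.normal(1.0, _ANIMAL_JITTER_CV),
                t1=cls.t1 * rng.normal(1.0, _ANIMAL_JITTER_CV),
                r2s=cls.r2s * abs(rng.normal(1.0, _ANIMAL_JITTER_CV)),
            )
    return out


def _roi_volume_estimate(roi: str, dims, rng: np.random.Generator) -> float:
    """Analytic ellipsoid voxel-count estimate with the same relative jitter
    the image-space geometry jitter produces (table-only cohorts)."""
    _, semi = _GEOMETRY[roi]
    scale = float(np.clip(rng.normal(1.0, 0.02), 0.9, 1.1))
    vol = 4.0 / 3.0 * np.pi * np.prod([s * n * scale for s, n in zip(semi, dims)])
    return float(vol)


def simulate_cohort(
    spec: CohortSpec,
    protocol: AcquisitionProtocol | None = None,
    build_phantoms: bool = True,
) -> CohortBundle:
    """Generate a two-genotype cohort with programmed ROI-level effects.

    Returns per-animal tissue parameter sets (and phantoms, unless
    ``build_phantoms`` is False for fast table-only studies) plus the
    ground-truth long-format table of per-animal ROI metric values.  The
    table (and everything else) is deterministic for a fixed spec seed.
    """
    protocol = protocol or AcquisitionProtocol()
    effect_table = (
        default_effect_table() if spec.effect_table is None else dict(spec.effect_table)
    )
    rng = np.random.default_rng(spec.seed)
    animals: list[AnimalRecord] = []
    rows = []
    for genotype in GENOTYPES:
        for i in range(spec.n_per_genotype):
            aid = f"{genotype}_{i + 1:02d}"
            aseed = int(rng.integers(2**31))
            arng = np.random.default_rng(aseed)
            classes = _sample_animal_classes(arng, genotype, effect_table)
            phantom = None
            if build_phantoms:
                phantom = build_phantom(
                    spec.dims, genotype, seed=aseed, effect_table=effect_table
                )
                phantom.class_table = {
                    cls.label: classes[cls.name]
                    for cls in phantom.class_table.values()
                }
            for roi in ROI_NAMES:
                cls = classes[roi]
                if phantom is not None:
                    volume = float(phantom.roi_masks[roi].sum())
                else:
                    volume = _roi_volume_estimate(roi, spec.dims, arng)
                truth_vals = {
                    "r2s": cls.r2s,
                    "chi": cls.chi,
                    "qt1": cls.t1,
                    "arex_amide": derive_arex_truth(cls, "amide", protocol.larmor_mhz),
                    "arex_noe": derive_arex_truth(cls, "noe", protocol.larmor_mhz),
                }
                for metric in METRICS:
                    rows.append(
                        {
                            "animal": aid,
                            "genotype": genotype,
                            "roi": roi,
                            "metric": metric,
                            "value": truth_vals[metric],
                            "roi_volume": volume,
                        }
                    )
            animals.append(AnimalRecord(aid, genotype, aseed, classes, phantom))
    truth = pd.DataFrame(rows)
    return CohortBundle(spec, protocol, animals, truth)
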