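"""End-to-end pipeline orchestration with validated configuration,
stage resumption, and a reproducible on-disk layout.

Stage order: simulate -> relaxometry -> qsm -> cest -> stats.  Every stage
reads only the previous stages' on-disk outputs, writes under its own
subdirectory of the output root, and records parameters, input hashes and
outputs in the run manifest.  Re-running with identical configuration and
seeds reproduces identical outputs (manifest wall-times excepted).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cest import (
    CESTGeometry,
    FivePoolModel,
    ZSpectrumStack,
    compute_arex,
    normalize_and_correct,
    resample_to_cest,
    wassr_b0_map,
)
from .phantom import METRICS, ROI_NAMES
from .protocol import AcquisitionProtocol
from .qsm import FieldMap, fit_fieldmap, invert_susceptibility, laplacian_unwrap, vsharp_filter
from .relaxometry import (
    QuantMap,
    arlo_r2star,
    csf_mask_from_qt1,
    despot1_qt1,
    te_weighted_combine,
)
from .simulate import CohortSpec, simulate_cohort, simulate_spgr_multiecho, simulate_zspectrum_stack
from .stats import (
    fit_lmem_genotype_roi,
    posthoc_genotype_by_roi,
    residualize_on_volume,
    roi_robust_mean,
)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger("mqmri")

STAGES = ("simulate", "relaxometry", "qsm", "cest", "stats")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``validate_config``)."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_per_genotype: int = 6
    dims: tuple[int, int, int] = (64, 64, 16)
    effect_table: dict | None = None
    noise_gre: float = 2.0
    noise_zspec: float = 5.0
    tr: float = 33.57
    field_strength: float = 9.4
    csf_cutoff_ms: float = 3000.0
    qsm_reg_param: float = 1e-3
    qsm_radii: tuple[int, ...] = (3, 2, 1)
    qsm_threshold: float = 0.05
    cest_n_slices: int = 4
    cest_fit_stride: int = 1
    cest_roi_only: bool = True
    trim: float = 0.05
    robust_method: str = "trim"
    n_boot: int = 1000

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(tr=self.tr, field_strength=self.field_strength)

    def cest_geometry(self) -> CESTGeometry:
        """CEST slab centered on the phantom volume (slices along z)."""
        dz = 0.25
        pitch = 0.5  # slice + gap
        extent = self.cest_n_slices * pitch - 0.25
        z0 = max(0.0, np.floor(((self.dims[2] * dz - extent) / 2.0) / dz) * dz)
        return CESTGeometry(n_slices=self.cest_n_slices, z0_mm=float(z0))

    def cohort_spec(self) -> CohortSpec:
        table = None
        if self.effect_table is not None:
            table = {
                tuple(k.split(":")): float(v) for k, v in self.effect_table.items()
            }
        return CohortSpec(
            n_per_genotype=self.n_per_genotype,
            effect_table=table,
            noise_sd={"gre": self.noise_gre, "zspec": self.noise_zspec},
            seed=self.seed,
            dims=tuple(self.dims),
        )


_SCHEMA = {
    "seed": (int, None),
    "stages": (list, None),
    "n_per_genotype": (int, lambda v: v >= 2 or "must be >= 2"),
    "dims": (list, lambda v: (len(v) == 3 and all(isinstance(d, int) and d >= 16 for d in v)) or "must be 3 ints >= 16"),
    "effect_table": (dict, None),
    "noise_gre": ((int, float), lambda v: v >= 0 or "must be >= 0"),
    "noise_zspec": ((int, float), lambda v: v >= 0 or "must be >= 0"),
    "tr": ((int, float), lambda v: v > 0 or "must be > 0"),
    "field_strength": ((int, float), lambda v: v > 0 or "must be > 0"),
    "csf_cutoff_ms": ((int, float), lambda v: v > 0 or "must be > 0"),
    "qsm_reg_param": ((int, float), lambda v: v >= 0 or "must be >= 0"),
    "qsm_radii": (list, lambda v: all(isinstance(r, int) and r >= 1 for r in v) or "radii must be ints >= 1"),
    "qsm_threshold": ((int, float), lambda v: 0 < v < 1 or "must be in (0, 1)"),
    "cest_n_slices": (int, lambda v: v >= 1 or "must be >= 1"),
    "cest_fit_stride": (int, lambda v: v >= 1 or "must be >= 1"),
    "cest_roi_only": (bool, None),
    "trim": ((int, float), lambda v: 0 <= v < 0.5 or "must be in [0, 0.5)"),
    "robust_method": (str, lambda v: v in ("trim", "winsorize") or "must be trim|winsorize"),
    "n_boot": (int, lambda v: v >= 100 or "must be >= 100"),
}


def validate_config(source) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a config mapping, YAML/JSON path, or YAML text.

    All problems are collected and returned together; the config object is
    None if any error was found.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    raw = raw or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    for key in raw:
        if key not in _SCHEMA:
            errors.append(f"{key}: unknown key")
    clean = {}
    for key, (types, check) in _SCHEMA.items():
        if key not in raw:
            continue
        val = raw[key]
        if val is None:
            clean[key] = None
            continue
        if not isinstance(val, types) or isinstance(val, bool) and types is int:
            errors.append(f"{key}: expected {types}, got {type(val).__name__}")
            continue
        if check is not None:
            ok = check(val)
            if ok is not True:
                errors.append(f"{key}: {ok}")
                continue
        clean[key] = val
    if "stages" in clean and clean["stages"] is not None:
        bad = [s for s in clean["stages"] if s not in STAGES]
        if bad:
            errors.append(f"stages: unknown stage(s) {bad}")
        else:
            clean["stages"] = tuple(clean["stages"])
    if "effect_table" in clean and clean["effect_table"] is not None:
        for k, v in clean["effect_table"].items():
            parts = str(k).split(":")
            if len(parts) != 2 or parts[0] not in ROI_NAMES or parts[1] not in METRICS:
                errors.append(f"effect_table: bad key {k!r} (expected 'roi:metric')")
            if not isinstance(v, (int, float)):
                errors.append(f"effect_table[{k}]: shift must be numeric")
    for tup_key in ("dims", "qsm_radii"):
        if tup_key in clean and clean[tup_key] is not None:
            clean[tup_key] = tuple(clean[tup_key])
    if errors:
        return None, errors
    return RunConfig(**clean), []


@dataclass
class RunManifest:
    """Per-run record: stage parameters, input hashes, outputs, timings."""

    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def record(self, stage: str, params: dict, inputs: dict, outputs: list, wall: float):
        self.stages[stage] = {
            "params": params,
            "input_hashes": inputs,
            "outputs": sorted(str(o) for o in outputs),
            "wall_time_s": round(wall, 3),
        }

    def write(self, path: Path):
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}, which stage '{stage}' produces; "
            f"run '{stage}' first"
        )
    return path


def _animal_ids(outdir: Path, needed_by: str) -> list[str]:
    cohort_json = _require(outdir / "simulate" / "cohort.json", "simulate", needed_by)
    return json.loads(cohort_json.read_text())["animals"]


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    proto = cfg.protocol()
    bundle = simulate_cohort(cfg.cohort_spec(), proto)
    sdir = outdir / "simulate"
    outputs = []
    geometry = cfg.cest_geometry()
    rng = np.random.default_rng(cfg.seed + 1)
    for rec in bundle.animals:
        adir = sdir / rec.animal_id
        ph = rec.phantom
        vs = ph.voxel_size_mm
        outputs.append(mio.save_volume(adir / "labels.nii", ph.label_volume, vs))
        outputs.append(mio.save_volume(adir / "b0_ppm.nii", ph.b0_offset, vs))
        for name, m in ph.roi_masks.items():
            outputs.append(mio.save_volume(adir / f"mask_{name}.nii", m.astype(float), vs))
        gres = simulate_spgr_multiecho(
            ph, proto, noise_sd=cfg.noise_gre, seed=int(rng.integers(2**31))
        )
        for fa, gre in gres.items():
            outputs.extend(mio.save_gre(adir / f"gre_fa{int(fa)}", gre, vs))
        for mode in ("cest", "wassr"):
            stack = simulate_zspectrum_stack(
                ph, proto, mode, noise_sd=cfg.noise_zspec, seed=int(rng.integers(2**31)),
                geometry=geometry,
            )
            sidecar = {
                "offsets_ppm": list(map(float, stack.offsets)),
                "reference_offset_ppm": proto.reference_offset,
                "n_slices": geometry.n_slices,
            }
            raw = stack.z * stack.reference_image[..., None]
            outputs.append(mio.save_volume(adir / f"{mode}_raw.nii", raw, vs, sidecar))
            outputs.append(mio.save_volume(adir / f"{mode}_ref.nii", stack.reference_image, vs))
    bundle.truth.to_csv(sdir / "truth.csv", index=False)
    outputs.append(sdir / "truth.csv")
    (sdir / "cohort.json").write_text(
        json.dumps({"animals": [r.animal_id for r in bundle.animals]}, indent=2)
    )
    outputs.append(sdir / "cohort.json")
    return outputs


def _stage_relaxometry(cfg: RunConfig, outdir: Path) -> list[Path]:
    outputs = []
    for aid in _animal_ids(outdir, "relaxometry"):
        adir = outdir / "simulate" / aid
        rdir = outdir / "relaxometry" / aid
        proto = cfg.protocol()
        fa_lo, fa_hi = sorted(proto.flip_angles)
        gre_lo = mio.load_gre(adir / f"gre_fa{int(fa_lo)}")
        gre_hi = mio.load_gre(adir / f"gre_fa{int(fa_hi)}")
        mag = gre_lo.magnitude()
        t2sw = te_weighted_combine(mag, gre_lo.echo_times)
        r2s = arlo_r2star(mag, gre_lo.echo_times)
        _, qt1 = despot1_qt1(gre_lo, gre_hi)
        csf = csf_mask_from_qt1(qt1, cfg.csf_cutoff_ms)
        outputs.append(mio.save_quantmap(rdir / "t2sw.nii", t2sw))
        outputs.append(mio.save_quantmap(rdir / "r2s.nii", r2s))
        outputs.append(mio.save_quantmap(rdir / "qt1.nii", qt1))
        outputs.append(
            mio.save_volume(rdir / "csf_mask.nii", csf.astype(float),
                            sidecar={"cutoff_ms": cfg.csf_cutoff_ms,
                                     "voxel_count": int(csf.sum())})
        )
    return outputs


def _stage_qsm(cfg: RunConfig, outdir: Path) -> list[Path]:
    outputs = []
    proto = cfg.protocol()
    fa_qsm = int(min(proto.flip_angles))  # low flip angle avoids T1 weighting
    for aid in _animal_ids(outdir, "qsm"):
        adir = outdir / "simulate" / aid
        qdir = outdir / "qsm" / aid
        _require(adir / f"gre_fa{fa_qsm}_mag.nii", "simulate", "qsm")
        gre = mio.load_gre(adir / f"gre_fa{fa_qsm}")
        labels, _ = mio.load_volume(adir / "labels.nii")
        mask = labels > 0
        fmap, resid = fit_fieldmap(gre)
        dte_s = proto.delta_te * 1e-3
        phase = 2.0 * np.pi * fmap.values * dte_s
        unwrapped = laplacian_unwrap(np.angle(np.exp(1j * phase)))
        f_hz = unwrapped / (2.0 * np.pi * dte_s)
        local, emask = vsharp_filter(
            FieldMap(f_hz * mask, mask), mask, cfg.qsm_radii, cfg.qsm_threshold
        )
        sus = invert_susceptibility(
            local, emask, cfg.qsm_reg_param, hz_per_ppm=proto.hz_per_ppm
        )
        outputs.append(mio.save_volume(qdir / "fieldmap_hz.nii", fmap.values,
                                       sidecar={"residual_flagged": int((~fmap.valid_mask).sum())}))
        outputs.append(mio.save_volume(qdir / "local_field_hz.nii", local.values))
        outputs.append(
            mio.save_volume(
                qdir / "chi_ppm.nii", sus.values,
                sidecar={"units": "ppm", "converged": sus.converged, **sus.info},
            )
        )
        outputs.append(mio.save_volume(qdir / "qsm_mask.nii", emask.astype(float)))
        (qdir / "convergence.json").write_text(
            json.dumps({"converged": bool(sus.converged), **sus.info})
        )
        outputs.append(qdir / "convergence.json")
    return outputs


def _stage_cest(cfg: RunConfig, outdir: Path) -> list[Path]:
    outputs = []
    proto = cfg.protocol()
    geometry = cfg.cest_geometry()
    for aid in _animal_ids(outdir, "cest"):
        adir = outdir / "simulate" / aid
        rdir = outdir / "relaxometry" / aid
        cdir = outdir / "cest" / aid
        wassr_raw, wassr_sc = mio.load_volume(adir / "wassr_raw.nii")
        wassr_ref, _ = mio.load_volume(adir / "wassr_ref.nii")
        cest_raw, cest_sc = mio.load_volume(adir / "cest_raw.nii")
        cest_ref, _ = mio.load_volume(adir / "cest_ref.nii")
        qt1 = mio.load_quantmap(_require(rdir / "qt1.nii", "relaxometry", "cest"))
        csf, _ = mio.load_volume(rdir / "csf_mask.nii")
        labels, _ = mio.load_volume(adir / "labels.nii")

        wassr_off = np.asarray(wassr_sc["offsets_ppm"], float)
        cest_off = np.asarray(cest_sc["offsets_ppm"], float)
        wassr_stack = ZSpectrumStack(
            np.clip(np.divide(wassr_raw, wassr_ref[..., None],
                              out=np.zeros_like(wassr_raw),
                              where=wassr_ref[..., None] > 0), 0, 1.2),
            wassr_off, wassr_ref, geometry,
        )
        b0 = wassr_b0_map(wassr_stack)
        stack = normalize_and_correct(cest_raw, cest_ref, cest_off, b0, geometry)

        qt1_cest = resample_to_cest(qt1, geometry)
        csf_cest = resample_to_cest(QuantMap(csf, "a.u."), geometry, is_mask=True)
        roi_cest = {}
        brain_fit = np.zeros(stack.z.shape[:-1], dtype=bool)
        for name in ROI_NAMES:
            m, _ = mio.load_volume(adir / f"mask_{name}.nii")
            rm = resample_to_cest(QuantMap(m, "a.u."), geometry, is_mask=True)
            roi_cest[name] = rm.values > 0.5
            brain_fit |= roi_cest[name]
        if not cfg.cest_roi_only:
            lab_cest = resample_to_cest(QuantMap((labels > 0).astype(float), "a.u."),
                                        geometry, is_mask=True)
            brain_fit = lab_cest.values > 0.5
        if cfg.cest_fit_stride > 1:
            stride_mask = np.zeros_like(brain_fit)
            stride_mask[:: cfg.cest_fit_stride, :: cfg.cest_fit_stride, :] = True
            brain_fit &= stride_mask
        fit = FivePoolModel(stack, proto.larmor_mhz, brain_fit).fit()
        # AREX evaluated at the nominal pool offsets (the +3.5 / -3.5 ppm map
        # convention); the fitted-center variant is unstable when a noisy
        # small pool's center drifts toward the water line
        arex = {
            "arex_amide": compute_arex(fit, qt1_cest, "amide", eval_offset=3.5,
                                       mask=brain_fit),
            "arex_noe": compute_arex(fit, qt1_cest, "noe", eval_offset=-3.5,
                                     mask=brain_fit),
        }
        outputs.append(mio.save_volume(cdir / "b0_ppm.nii", b0.values))
        for pool in ("water", "noe", "mt", "amide", "amine"):
            outputs.append(
                mio.save_volume(cdir / f"amplitude_{pool}.nii", fit.amplitude_map(pool))
            )
        for name, qm in arex.items():
            outputs.append(mio.save_quantmap(cdir / f"{name}.nii", qm))
        for name, m in roi_cest.items():
            outputs.append(mio.save_volume(cdir / f"mask_{name}.nii", m.astype(float)))
        outputs.append(mio.save_volume(cdir / "mask_csf.nii", csf_cest.values.astype(float)))
        diag = pd.DataFrame(
            {
                "voxel": [str(tuple(v)) for v in np.argwhere(brain_fit)],
                "residual_rms": fit.residual_rms[brain_fit],
                "converged": fit.converged[brain_fit],
            }
        )
        diag.to_csv(cdir / "fit_diagnostics.csv", index=False)
        outputs.append(cdir / "fit_diagnostics.csv")
    return outputs


def _stage_stats(cfg: RunConfig, outdir: Path) -> list[Path]:
    sdir = outdir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for aid in _animal_ids(outdir, "stats"):
        adir = outdir / "simulate" / aid
        rdir = outdir / "relaxometry" / aid
        qdir = outdir / "qsm" / aid
        cdir = outdir / "cest" / aid
        _require(rdir / "qt1.nii", "relaxometry", "stats")
        _require(qdir / "chi_ppm.nii", "qsm", "stats")
        _require(cdir / "arex_noe.nii", "cest", "stats")
        genotype = aid.split("_")[0]
        csf, _ = mio.load_volume(rdir / "csf_mask.nii")
        csf = csf > 0.5
        maps3d = {
            "r2s": mio.load_quantmap(rdir / "r2s.nii").values,
            "qt1": mio.load_quantmap(rdir / "qt1.nii").values,
            "chi": mio.load_volume(qdir / "chi_ppm.nii")[0],
        }
        qsm_mask = mio.load_volume(qdir / "qsm_mask.nii")[0] > 0.5
        csf_cest = mio.load_volume(cdir / "mask_csf.nii")[0] > 0.5
        for roi in ROI_NAMES:
            roi3d = mio.load_volume(adir / f"mask_{roi}.nii")[0] > 0.5
            volume = int((roi3d & ~csf).sum())
            for metric in ("r2s", "qt1", "chi"):
                m = roi3d if metric != "chi" else (roi3d & qsm_mask)
                val, _n = roi_robust_mean(
                    maps3d[metric], m, csf, cfg.trim, cfg.robust_method
                )
                rows.append(dict(animal=aid, genotype=genotype, roi=roi,
                                 metric=metric, value=val, roi_volume=volume))
            roi_c = mio.load_volume(cdir / f"mask_{roi}.nii")[0] > 0.5
            for metric, fname in (("arex_amide", "arex_amide.nii"),
                                  ("arex_noe", "arex_noe.nii")):
                qm = mio.load_quantmap(cdir / fname)
                m = roi_c & (qm.valid_mask if qm.valid_mask is not None else True)
                val, _n = roi_robust_mean(qm.values, m, csf_cest, cfg.trim,
                                          cfg.robust_method)
                rows.append(dict(animal=aid, genotype=genotype, roi=roi,
                                 metric=metric, value=val, roi_volume=volume))
    table = pd.DataFrame(rows)
    table.to_csv(sdir / "roi_table.csv", index=False)
    outputs = [sdir / "roi_table.csv"]

    report = {}
    lmem_rows = []
    for metric in METRICS:
        resid = residualize_on_volume(table, metric)
        sub = table.loc[resid.index].copy()
        sub["value"] = resid.to_numpy()
        res = fit_lmem_genotype_roi(sub)
        ph = posthoc_genotype_by_roi(res, n_boot=cfg.n_boot, seed=cfg.seed)
        for term, row in res.anova.iterrows():
            lmem_rows.append({"metric": metric, "term": term, **row.to_dict()})
        ph.table.to_csv(sdir / f"posthoc_{metric}.csv")
        outputs.append(sdir / f"posthoc_{metric}.csv")
        report[metric] = {
            "genotype_p": float(res.anova.loc["genotype", "p"]),
            "interaction_p": float(res.anova.loc["genotype:roi", "p"]),
            "singular": res.singular,
        }
    pd.DataFrame(lmem_rows).to_csv(sdir / "lmem_summary.csv", index=False)
    outputs.append(sdir / "lmem_summary.csv")
    (sdir / "report.json").write_text(json.dumps(report, indent=2))
    outputs.append(sdir / "report.json")
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "relaxometry": _stage_relaxometry,
    "qsm": _stage_qsm,
    "cest": _stage_cest,
    "stats": _stage_stats,
}


def run_pipeline(
    config: RunConfig, outdir: Path | str, resume: bool = False
) -> RunManifest:
    """Execute the configured stages in dependency order.

    With ``resume`` a stage whose ``.done`` marker exists is skipped; a stage
    whose upstream outputs are missing fails with an error naming the stage
    to run first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.seed, asdict(config))
    for stage in STAGES:
        if stage not in config.stages:
            continue
        marker = outdir / stage / ".done"
        if resume and marker.exists():
            log.info("stage %s: up to date, skipping", stage)
            continue
        log.info("stage %s: running", stage)
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](config, outdir)
        inputs = {}
        if stage != "simulate":
            cohort_json = outdir / "simulate" / "cohort.json"
            if cohort_json.exists():
                inputs[str(cohort_json)] = mio.file_hash(cohort_json)
        manifest.record(stage, asdict(config), inputs, outputs, time.time() - t0)
        marker.parent.mkdir(parents=True, exist_ok=True)
        marker.write_text("ok")
        log.info("stage %s: done (%.1fs)", stage, time.time() - t0)
    manifest.write(outdir / "manifest.json")
    return manifest
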