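# mqmri

Multimodal quantitative MRI analysis for preclinical (9.4 T mouse) brain
imaging, built around a synthetic digital-phantom test bed so that every
stage can be verified against known ground truth.

The package is aimed at researchers studying amyloid-driven tissue changes
in transgenic mouse models (e.g., the ARTE10 APP/PSEN1 line) with a
multiparametric protocol: multiecho spoiled gradient-echo (SPGR) imaging at
two flip angles, saturation-transfer (CEST) imaging, and a WASSR B0 sweep.
From those acquisitions it computes, per animal:

- **R2\*** via the ARLO estimator (auto-regression on linear operations) for
  equally spaced echoes, recalibrated analytically so that noiseless
  monoexponential decays are inverted exactly;
- **qT1** via two-flip-angle DESPOT1 extended to multiecho data (per-echo T1
  from the SPGR linearization, then a signal-weighted average over echoes),
  plus the qT1 > 3000 ms CSF mask;
- **χ (QSM)** via per-voxel nonlinear complex field fitting, Laplacian phase
  unwrapping, V-SHARP background-field removal and Tikhonov-regularized
  dipole inversion;
- **CEST/AREX** via WASSR B0 correction and a two-stage five-pool fit
  (direct water saturation, super-Lorentzian MT, amide +3.5 ppm, amine
  +2.0 ppm, relayed NOE −3.5 ppm), with AREX maps
  `AREX = (1/Z_corr − 1/Z_ref) · (1/T1)` in s⁻¹;
- **group statistics**: ROI-volume residualization, a REML linear
  mixed-effects model `value ~ genotype * ROI + (1 | animal)` with type III
  F tests and Satterthwaite degrees of freedom, Benjamini–Hochberg-corrected
  post hoc genotype contrasts per ROI, Hedges' g with cluster-bootstrap CIs,
  exact Mann–Whitney / Fisher tests, and partial correlations.

The five-pool Z-spectrum model is

```
Z(Δω) = 1 − Σᵢ Aᵢ / (1 + 4 (Δω − Δωᵢ)² / σᵢ²) − A_SL · ĝ(Δω − Δω_SL; T2MT)
```

with Lorentzian amplitudes `Aᵢ`, FWHM `σᵢ` (ppm) and centers `Δωᵢ`, and a
super-Lorentzian MT lineshape `ĝ` normalized to its (spline-bridged) center
value so `A_SL` is the peak MT saturation fraction.  All parameters are
constrained to a published bounds table during fitting.

## Worked example

```python
import numpy as np
from mqmri import AcquisitionProtocol, build_phantom
from mqmri.simulate import simulate_zspectrum_stack
from mqmri.cest import CESTGeometry, FivePoolModel

protocol = AcquisitionProtocol()          # 9.4 T defaults, 75-point Z-grid
phantom = build_phantom((16, 16, 16), "WT", seed=3)
geometry = CESTGeometry(n_slices=2, z0_mm=1.5)
stack = simulate_zspectrum_stack(phantom, protocol, "cest", geometry=geometry)

mask = np.zeros(stack.z.shape[:-1], bool)
mask[3, 8, 0] = True                      # one brain-tissue voxel
fit = FivePoolModel(stack, protocol.larmor_mhz, mask).fit()
for pool in ("water", "noe", "amide", "amine", "mt"):
    print(pool, round(float(fit.params[pool][3, 8, 0][0]), 4))
```

prints

```
water 0.85
noe 0.05
amide 0.03
amine 0.03
mt 0.08
```

i.e., on noiseless input the fitted pool amplitudes recover the phantom's
generative values exactly (the joint refinement stage drives the residual
to machine precision when the data are noise-free).

The full pipeline runs from the command line:

```sh
mqmri all --outdir run1 --seed 7
mqmri stats --outdir run1 --seed 7 --resume   # re-run a single stage
```

producing per-animal NIfTI maps under `run1/<stage>/<animal>/` and the
group-statistics tables (`roi_table.csv`, `lmem_summary.csv`,
`posthoc_<metric>.csv`) under `run1/stats/`.

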