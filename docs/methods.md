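# Methods

## Scope and design

`mqmri` reimplements a multiparametric quantitative-MRI analysis for mouse
brain at 9.4 T — relaxometry (R2*, qT1), quantitative susceptibility mapping
(QSM), multi-pool CEST/AREX quantification, and a genotype × ROI statistical
stage — together with a forward simulator that generates every input the
analysis consumes.  The simulator exists so that each stage can be verified
against exact ground truth: its generative models are precisely the models
the analysis stages invert, which turns parameter recovery into a sharp
numerical test rather than a qualitative comparison.

## Acquisition protocol

`AcquisitionProtocol` records the timing shared by all stages: eight echoes
at TE₁ = 2.177 ms with ΔTE = 2.47 ms, TR = 33.57 ms, flip angles 15° and
40°, 9.4 T (Larmor ≈ 400.2 MHz; 1 ppm ≈ 400.2 Hz).  The CEST fitting grid
is the uniform −8..+8 ppm grid at 0.25 ppm (65 points) plus ten far offsets
at ±16/±25/±50/±100/±200 ppm, with an unsaturated reference at −300 ppm that
is used only for normalization.  The WASSR sweep covers −1..+1 ppm at
0.05 ppm.  Saturation power (1 μT) and durations (5000/1000 ms) are recorded
metadata; the lineshape model below does not consume them.

## Digital phantom and cohorts

The phantom is an ellipsoidal "brain" with four ellipsoidal gray/white
tissue ROIs (hippocampus, corpus callosum, thalamus, striatum) and a central
CSF compartment on a 64×64×16 grid (0.25 mm isotropic) by default.  Geometry
is deliberately schematic: every algorithm downstream is geometry-agnostic,
and small grids keep the full pipeline testable in minutes.  Each tissue
class carries M0, T1 (ms), R2* (1/s), χ (ppm) and a five-pool CEST parameter
set; values are plausible for mouse brain at 9.4 T (tissue T1 ≈ 1.7–1.9 s,
CSF T1 = 3.5 s, tissue R2* ≈ 28–34 s⁻¹, |χ| ≤ 0.015 ppm).  A smooth
random B0 offset field (three broad Gaussian blobs, ±0.15 ppm) drives the
WASSR/CEST frequency-shift machinery.

Two-genotype cohorts program group differences through an effect table in
within-group standard-deviation units per (ROI, metric).  The default
effect table follows the effect-size pattern reported for the ARTE10
amyloidosis model: higher hippocampal χ (+1.99 SD) and R2* (≈+1.2 SD in all
ROIs), higher thalamic qT1 (+1.84 SD), and reduced NOE/amide AREX
(−1.1..−2.6 SD).  Within-group SDs are 2% coefficients of variation for
R2*/qT1, an absolute 0.0015 ppm for χ (its mean is near zero), and 4% for
the CEST pool amplitudes.  Each animal's ROI value decomposes as
mean + shift + animal effect + ROI-level noise, with the shared animal
component carrying half the within-group variance — this is the random
intercept the mixed model later estimates.  ROI volumes vary between
animals through a ±2% jitter of the ellipsoid axes.

The simulator evaluates closed-form models: SPGR steady state
M0·sinα(1−E1)/(1−E1·cosα)·exp(−TE·R2*) with phase 2π·f·TE + φ0, f being the
forward dipole field of χ; and the five-pool Z-spectrum evaluated at
(Δω − B0) per voxel.  Bloch–McConnell time-domain saturation is
intentionally out of scope: passing tests demonstrate correct inversion of
the lineshape model, not robustness to saturation-physics model error,
B1 inhomogeneity, motion, or partial-volume effects — none of which the
phantom emulates.

## Relaxometry

**Coil combination.** Magnitude is the RMS over channels; phase uses the
phase-difference convention (echo-1 phase defined zero; later echoes from
Σ_ch s_j·conj(s_1)), which cancels channel-specific phase offsets.

**TE-weighted combination.** Weights ω_i = TE_i²·S_i² emphasize late-echo
T2* contrast; the output is the weighted mean over echoes.

**ARLO R2*.** The estimator regresses Simpson-rule triplet integrals against
signal differences (equally spaced echoes only; unequal spacing is a hard
error).  On a pure exponential the raw estimate equals
(ΔTE/3)(1+4a+a²)/(1−a²) with a = exp(−ΔTE·R2*) — a quadratic in a that we
invert analytically.  This recalibration removes the Simpson-quadrature bias
(up to 3×10⁻⁴ relative at R2* = 200 s⁻¹ on this echo grid) so that noiseless
decays match log-linear least squares to machine precision, while retaining
ARLO's noise-pooling structure.  Negative estimates are clipped to zero and
flagged.

**DESPOT1 qT1.** Per echo, E1 is the slope of S/sinα vs S/tanα through the
two flip-angle points; T1 = −TR/ln E1.  The exp(−TE·R2*) factor cancels, so
per-echo T1 values agree on noiseless data.  The echo average uses weights
w_i = mean over the two flip angles of S_i² — signal weighting without the
TE² factor, which would bias toward late echoes.  Voxels with E1 outside
(0, 1) are masked.  The CSF mask is qT1 strictly greater than 3000 ms.

## QSM

The dipole kernel is D(k) = 1/3 − k_z²/|k|² with D(0) = 0 (mean-field
reference convention); the same kernel serves the simulator's forward model
and the inversion.  Field maps come from a per-voxel nonlinear
least-squares fit of s_j = a·exp(iφ0 + i2πf·TE_j): amplitude and φ0 are
profiled out analytically and f is polished by Newton iterations on the
concentrated objective |Σ_j s_j e^(−i2πf TE_j)|², initialized from the
echo-1/2 phase difference.  With equally spaced echoes f is identifiable
only modulo 1/ΔTE; estimates are reported in the principal interval.
Voxels whose normalized fit residual exceeds 0.25 are flagged.

Laplacian unwrapping solves ∇²ψ = cosφ·∇²sinφ − sinφ·∇²cosφ by FFT with a
zeroed DC term (periodic boundaries); a three-voxel boundary band is always
excluded from quantitative use.  V-SHARP removes background fields by
spherical-mean-value filtering with kernel radius shrinking toward the mask
boundary (default radii 3→1 voxels), followed by truncated deconvolution of
the largest kernel (threshold 0.05) and a three-voxel mask erosion.  Radii
and threshold are configuration-exposed; small kernels truncate more
low-frequency local field, so analyses of broad sources should increase the
radii.

Dipole inversion minimizes ‖M(F⁻¹DF(Mχ) − f)‖² + λ‖χ‖² by conjugate
gradients (λ = 10⁻³ by default, 300-iteration cap, relative tolerance 10⁻⁸,
convergence flagged).  The unknowns are restricted to the mask support —
after background removal all remaining sources are assumed internal; without
this restriction the masked observation leaves a large null space and
interior round-trip errors roughly double.  Output is referenced to mean
zero over the mask.  Only the 15° acquisition feeds QSM (the lower flip
angle minimizes T1 weighting).

## CEST / AREX

**Lineshapes.** Lorentzian pools use A/(1 + 4(Δω−Δω₀)²/σ²) with σ the FWHM
in ppm.  The MT pool uses the super-Lorentzian absorption integral over
fiber orientation, evaluated by composite Gauss–Legendre quadrature in
u = cosθ with panels geometrically graded toward the magic-angle zero and
the u = 1 boundary layer (relative accuracy ~10⁻¹³ against adaptive
quadrature across the full T2MT bound range of 1–50 μs).  The integrand
diverges at the line center, so the inner |Δω − Δω_SL| < 8 ppm region is
bridged by a cubic spline through quadrature anchors at ±{8, 10, 12, 16,
25, 50, 100, 200} ppm.  The lineshape is normalized by its bridged center
value, making A_SL the peak saturation fraction — dimensionally consistent
with the Lorentzian amplitudes and with the [0, 1] amplitude bounds; the
raw integral (units of seconds) would contribute only ~10⁻⁵ to Z with those
bounds.

**Bounds.** All fits are constrained to the tabulated per-pool
lower/upper/start values (water A 0.02–1 start 0.9, σ 0.3–10 ppm start 1.4,
center ±1 ppm; NOE A 0–0.6, σ 0.5–10, center −4–0; MT A 0–1, T2MT 1–50 μs,
center ±4 ppm; amide A 0–2, σ 0.4–4, center 3–4 ppm; amine A 0–0.2,
σ 0.5–5, center 1.75–2.25 ppm).  Fitted values can never leave the box
(trust-region-reflective least squares).

**B0 correction.** WASSR spectra are spline-interpolated to a 0.001 ppm
grid and the minimum location taken as the voxel B0 (flat spectra masked).
The CEST stack is normalized by the unsaturated reference and
re-interpolated from effective offsets (nominal − B0) back onto the nominal
grid, holding edge values outside the sampled range; |B0| > 0.5 ppm flags
the voxel.

**Two-stage fit.** Stage 1 fits water + MT to the points strictly outside
±8 ppm (including the ±8 ppm edge points would let NOE tails bias A_SL by
~3%).  Stage 2 refits all fifteen pool parameters jointly over the full
grid, seeded from the stage-1 water/MT estimates; the water center restarts
at 0 (far offsets barely constrain it).  The stage-1 estimates are used as
starting values rather than frozen constants because an MT amplitude
estimated from ten far-offset points alone is very noisy at realistic SNR
(spread 0.02–0.25 for a true 0.08 at Z-spectrum SNR 100), and a badly
frozen baseline forces the NOE pool into blow-up local minima.  If the
joint residual RMS exceeds 3×10⁻³ — several times any realistic noise
floor — the fit is retried from the tabulated starting vector and from a
variant with the NOE pool started at its canonical −3.5 ppm position, and
the lowest-residual solution kept.  This multi-start guard removes the
role-swap minima entirely in the SNR-100 verification (NOE amplitude bias
~3%, no outliers); on noiseless data the joint fit recovers the generative
parameters to machine precision.  A genuinely zero-amplitude NOE pool is
still not point-identified (its Lorentzian can coincide with water's); the
water + NOE amplitude sum is, and that is what the tests assert.

**AREX.** Z_ref re-evaluates the fitted model with the pool of interest
removed; AREX = (1/Z_corr − 1/Z_ref)/T1 with T1 in seconds (qT1 resampled
to the CEST geometry: in-plane identity, through-plane box average over
each 0.25 mm slice span, slice gaps carrying no data; masks re-binarized at
0.5 occupancy).  The pipeline evaluates AREX at the nominal pool offsets
(+3.5, +2.0, −3.5 ppm): evaluating at the fitted center is available through
``compute_arex`` but is unstable when a noisy small pool's center drifts
toward the water line, where 1/Z diverges.

## Statistics

**ROI summaries.** Robust ROI means exclude CSF voxels, then trim the
lowest and highest floor(n·0.05) values (removal, not clamping — a
winsorizing variant that clamps instead is available via configuration).

**Residualization.** Each metric is regressed (pooled OLS) on ROI indicator
variables plus ROI volume; residuals feed the model stage.  Including the
ROI indicators forces the mixed-model ROI main-effect F to zero by
construction, isolating genotype and interaction effects — volume-only
residualization would not guarantee this.

**Mixed model.** value ~ genotype * ROI with a random intercept per animal,
estimated by REML (the compound-symmetric per-animal covariance is handled
in closed form; the two variance components are optimized by Nelder–Mead
with an explicit boundary check at σ²_animal = 0, flagged as singular).
Fixed effects use sum-to-zero coding so type III tests reduce to testing
each term's coefficients.  Denominator degrees of freedom follow the
Satterthwaite approach: for each contrast, ν = 2·Var(c'β)²/(g'Ag) with g
the gradient of the contrast variance in the variance components and A the
inverse REML information (finite differences); multi-df terms combine the
eigen-direction νs as ddf = 2E/(E−q), E = Σν/(ν−2).  The implementation was
validated against R lme4/lmerTest/emmeans on a frozen dataset (variance
components, F statistics, numerator/denominator dfs, p-values, and per-ROI
contrasts agree to the printed precision); those values are frozen in the
test suite.  On balanced designs the dfs reduce to the classical split-plot
values (10 for genotype, 30 for the interaction with 12 animals × 4 ROIs).

**Post hoc.** Per-ROI genotype contrasts are estimated-marginal-mean
differences from the fitted model, tested with Satterthwaite-df t tests and
Benjamini–Hochberg-adjusted across the four ROIs per metric.  Hedges'
g = J·Δ/s_pooled, J = 1 − 3/(4·df − 1), with a percentile CI from 1000
stratified cluster-bootstrap resamples (animals resampled with replacement
within genotype).

**Exact tests.** The Mann–Whitney U (pairs with x > y; midranks for ties)
takes its two-sided p from full enumeration of all C(n,n_x) group labelings,
doubling the smaller tail and capping at 1; rank-biserial r = 1 − 2U/(n_x
n_y), negative when the first group tends larger.  Fisher's exact test uses
the point-probability rule (via scipy, cross-checked by enumeration in the
tests).  Partial correlation uses the first-order formula with a t test on
n − 3 df (cross-checked against residual-on-residual Pearson and pingouin).

## Verification problem sizes

The acceptance surface uses: a 100-voxel noiseless CEST stack with
parameters drawn across the physically valid interior of the bounds box;
R2* ∈ [5, 200] s⁻¹ and T1 ∈ [200, 5000] ms sweeps for relaxometry
exactness; a 64³ smooth-χ round trip for QSM (interior RMSE < 5% of the χ
range after 3-voxel erosion); 1000 table-level null cohorts for the
mixed-model type-I error (0.05 ± 0.02) and 2000 replicates for the Hedges'
g expectation (a +2 SD programmed shift gives E[g] = 2·J·E[σ/s_p] ≈ 2.001
at n = 6+6); and a full 6-vs-6 image pipeline on a 32×32×16 phantom with
two CEST slices and a stride-2 fitting mask, plus 200 table-level replicate
cohorts for programmed-direction recovery of significant post hoc
contrasts.  These sizes were chosen so the whole suite verifies every claim
in minutes on a single core.

## Known limitations

- Saturation physics is phenomenological: amplitudes are descriptive pool
  weights, not exchange rates; no B1 correction is modeled.
- The phantom has no partial-volume mixing, motion, or coil-sensitivity
  structure; in-plane CEST resolution equals the GRE grid.
- The QSM inversion is plain Tikhonov-regularized least squares; no
  streaking-artifact refinement is applied, and susceptibility anisotropy
  is not modeled.
- The exact Mann–Whitney enumeration is limited to group totals whose
  C(n, n_x) stays below ~5×10⁶ (n ≈ 25 balanced).
- Field maps from equally spaced echoes are identifiable only modulo
  1/ΔTE ≈ 405 Hz; phantom fields stay far inside the principal interval.
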