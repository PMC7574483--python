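# Methods

This note documents the models implemented in `vfdrive`, the conventions
chosen where the field has none, and what the synthetic-data tests do and
do not demonstrate.

## Test-pattern geometry

Grids live in visual-field coordinates (degrees of visual angle; +x =
subject's right, +y = superior), the frame of a Humphrey printout. Both
eyes share the frame, so binocular overlay is coordinate-identical; only
two features are eye-specific:

* the blind spot (temporal field): x = +15, y = ±3 for OD; x = −15 for OS;
* the 24-2 nasal extension: two points at 27° on the nasal side
  (x = −27 for OD, +27 for OS).

`build_pattern` therefore returns per-eye grids. The 24-2 is the set of
odd multiples of 3° with |x|,|y| ≤ 21 and |x|+|y| ≤ 30 (52 points, mirror
symmetric) plus the nasal pair — 54 locations; the 30-2 is |x|,|y| ≤ 27
with |x|+|y| ≤ 36 — 76 locations, fully symmetric. OD and OS grids are
exact mirror images, so weight sums and all derived indices are
laterality-invariant.

### Ring weighting

The VFI weighting uses five concentric rings with weights 3.29, 1.28,
0.79, 0.57, 0.45 from center outward. Ring *membership* is not
standardized in print, so the package fixes default eccentricity
boundaries at **5.7°, 12.8°, 19.0°, 25.5°**, chosen so that on the 24-2:

| ring | locations | example |
|---|---|---|
| 1 | the central four (|x|=|y|=3, ecc 4.24°) | weight 3.29 |
| 2 | 12 points, ecc 9.5–12.8° | (3,9), (9,9) |
| 3 | 16 points, ecc 15.3–17.5° | (15,3), (9,15) |
| 4 | 20 points, ecc 21.2–22.8° | (21,3), (15,15) |
| 5 | the nasal pair, ecc 27.2° | (−27,±3) |

Anything beyond the last boundary falls in ring 5, which lets 30-2 grids
reuse the same convention (their outermost annulus joins ring 5). The
boundaries are a documented convention, configurable per call, not a
claim about any instrument's internal ring table. Blind-spot locations
carry weight 0: a physiologic absolute scotoma is uninformative about
disease.

## Binocular integration

The four equations (bTV, b̄TV, bTD, S) are implemented exactly as printed
in the package README, with base-10 dB↔linear conversion and no
1/Lambert rescaling. Numerical decisions:

* **Clamping S at 0.** The raw sensitivity formula goes negative when
  |bTD| > b̄TV (deep absolute defects). The index is defined on 0–100%,
  so S is floored at 0. This is the only point where the implementation
  deviates from the literal formula.
* **Single-eye locations.** A location may be seen by one eye only (the
  fellow eye's blind spot; the nasal pair; 24-2/30-2 mismatches). The
  quadratic sum has no attainable single-eye limit in dB space — a blind
  eye would contribute 10^(−∞), not 0 dB — so the seeing eye's TV/TD pass
  through unchanged (bTV = TV, b̄TV = TV − TD). This is the consistent
  limit of the formulas as the missing eye's linear sensitivity → 0.
* **Mixed patterns.** A 24-2/30-2 pair integrates on the 24-2 lattice
  (their intersection); the 30-2-only annulus is discarded rather than
  extrapolated.
* **Degenerate normative values.** b̄TV ≤ 0 (an expected threshold at or
  below 0 dB) makes the relative-deficit transform meaningless and is
  rejected rather than silently clamped.
* **Sub-zero thresholds.** Instrument "<0" codes must be converted to
  numbers upstream; the integration accepts any finite dB value.
* Equality tolerances throughout: 1e-6 dB / 1e-6 percentage points.

The implementation is verified per-location against an independent
scalar-arithmetic oracle on random field pairs, and obeys three provable
properties: the binocular gain bound (≤ 10·log10 √2 ≈ 1.50515 dB over
the better eye), exact eye-swap symmetry, and monotonicity of OU-VFI in
any single location's deviation.

## Driving-simulator metrics

"Variability" is the **sample standard deviation (ddof = 1) over the full
drive** — the standard lane-maintenance dispersion metric; no detrending
or segmentation is applied, and a pipeline aggregating repeated drives
should do so at the model stage (random intercepts), not by pooling
samples. Over-limit fractions use strict `speed > limit`, with 55 mph =
24.5872 m/s and 60 mph = 26.8224 m/s (1 mph = 0.44704 m/s exactly).
Acceleration channels are unit-agnostic: simulator exports use native
units whose absolute scale does not affect SD-based inference.

The DSVF detection task passes a location when hits/presentations is
**strictly** greater than 0.5 (3/4 passes, 2/4 fails). The simulator VFI
applies the same five-ring weighting to the binary pass map (pass = 100,
fail = 0) on a default 40-location lattice spanning 60°×20°
(x ∈ ±{3..27}, y ∈ ±{3,9}); because that grid is flat rather than
circular, eccentricity is scaled anisotropically (y × 3) before ring
lookup so the rings span the grid's vertical extent. Both the lattice
and the scaling are package conventions, configurable and documented
here rather than inherited from any published table.

Synthetic telemetry models each channel as its target value plus
stationary AR(1) noise (autocorrelation 0.98 per sample at 60 Hz,
matching the slow wander of real lane-keeping) with the requested
marginal SD; a 600 s drive has an effective sample size near 360, so the
planted SD is recovered within ~5–10%.

## Synthetic cohorts

The generator emulates the study design the analysis stage expects:
25 glaucoma subjects and 18 suspects by default, two drives each.

* **Fields.** Expected TV is a linear hill of vision: 30 dB at fixation
  declining 0.5 dB per 3° of eccentricity. TV = expected + archetype
  offset + Gaussian noise (SD 1.5 dB — a typical test-retest figure;
  perimetric noise is actually defect-depth-dependent, which is not
  modelled). TD = TV − expected holds exactly by construction. Defect
  archetypes: `normal` (0 dB), `early_arcuate` (−8 dB superior arcuate,
  ecc 9–22°), `nasal_step` (−10 dB superior nasal step), `moderate_diffuse`
  (−6 dB everywhere), `advanced` (−25 dB superior hemifield over −10 dB
  inferior). Suspects always get `normal`; glaucoma subjects draw from a
  0.3/0.2/0.3/0.2 mixture of the rest, with up to 4 dB of inter-eye
  asymmetry. The resulting glaucoma OU-VFI distribution spans roughly
  35–95%, straddling 50%.
* **Outcomes.** log(steering SD) and log(lateral-acceleration SD) are
  linear in age, worst-eye acuity, logit OU-VFI, MoCA total and VFQ
  driving, plus a per-subject random intercept (SD 0.30) and residual
  noise (SD 0.35). The default coefficients (e.g. −0.1875 per logit of
  OU-VFI on log steering SD) are the magnitudes reported for this study
  design, so parameter-recovery tests double as soft consistency checks.
  The residual/intercept SDs are not published; they were fixed once from
  the magnitude of typical reported standard errors.
* Covariate distributions (ages 69.8 ± 11.3 vs 60.3 ± 13.1, MoCA, VFQ,
  acuity) match the descriptive statistics typical of such cohorts, with
  hard clamps at instrument ranges.

What passing tests therefore show: the pipeline recovers effects it
plants, under Gaussian dB noise, lognormal outcomes, and a correctly
specified mean model. What they do not show: robustness to real
perimetric noise (frequency-of-seeing curves, fatigue, learning),
informative missingness, or model misspecification.

## Statistical stages

* **Pooled vs Welch t-tests** are selected by a Levene pre-check at
  α = 0.05 (configurable); MoCA uses Wilcoxon rank-sum, gender
  chi-square, correlation screens Spearman.
* **Logit transform** of OU-VFI clamps p = VFI/100 into [ε, 1−ε] with
  ε = 0.005, keeping intact fields (100%) finite at logit 5.29 while
  preserving order. Results for near-ceiling groups are mildly sensitive
  to ε; it is a config parameter.
* **Mixed models** are fit by REML (random intercept per subject) through
  statsmodels, with covariates standardized internally for optimizer
  stability and estimates mapped back exactly (tests assert the
  affine-invariance this guarantees). Denominator df use the
  **between-within allocation**: every covariate in these models is
  constant within subject, so each fixed effect is tested on
  n_subjects − rank(between design) df. This is a small-sample df
  convention in its own right; the package's simulation calibration
  (95% CI coverage ≈ 0.95 at n = 200; type-I p-values uniform at the
  default cohort size) measures its adequacy directly. With a single
  drive per subject the random intercept is unidentifiable and the fit
  degrades to OLS with a logged notice.
* **Cohen's d** is 2t/√df for continuous terms and the adjusted
  difference in log-means over the pooled residual SD for the group
  term; the formula used is implied by the term type.
* **No multiplicity correction** is applied; significance is the plain
  p < 0.05 convention of the exploratory design.
* **Missing data** are dropped listwise with a warning; no imputation.

## Reproducibility

Every pipeline run records its config hash (output directory excluded),
master seed and package version; all RNG streams descend from the master
seed via `numpy` SeedSequence spawning; CSV floats are printed at 6
significant digits, making reruns byte-identical.

## Known limitations

* The ring-boundary and DSVF-grid conventions are package choices, not
  instrument specifications; alternative conventions shift OU-VFI by a
  few points and should be fixed per study.
* Monocular TD values are consumed, never re-derived from a normative
  database; pointwise probability maps and progression analyses are out
  of scope.
* The between-within df approximation can differ from Kenward-Roger
  under unbalanced missingness; with the balanced designs generated here
  the two coincide closely.
* Lane position itself is not reconstructed; steering and lateral
  acceleration variability are its proxies.
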