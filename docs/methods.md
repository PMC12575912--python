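# Methods

This note documents the models, calibration choices and numerical details
behind `lvikit`, and what its synthetic-data tests do and do not
demonstrate about real PET/MRI data.

## Signal models

**IVIM.** The bi-exponential model
S_b/S₀ = (1 − f)·exp(−bD) + f·exp[−b(D* + D)] with the perfusion
compartment decaying at the *total* rate D* + D. Parameters: true
diffusion coefficient D (mm²/s, > 0), pseudo-diffusion coefficient D*
(≥ D), perfusion fraction f ∈ [0, 1]. Default acquisition: b = 0, 25, 50,
100, 150, 200, 400, 600, 800, 1000 s/mm².

**DKI.** ln(S_b/S₀) = −b·D_app + b²·D_app²·K_app/6 with D_app > 0,
K_app ≥ 0. The quadratic log-signal is a truncated cumulant expansion
valid for b ≤ 3/(D_app·K_app); beyond that bound the modeled signal turns
upward, which is physically meaningless but algebraically well defined.
The default 4-point scheme (b = 0, 500, 1000, 2000 s/mm²) exceeds the
bound for some realistic parameter combinations (e.g. D_app = 2.29×10⁻³
mm²/s, K_app = 0.84 → bound ≈ 1560 s/mm²). The forward model therefore
*warns* by default and evaluates the quadratic anyway — mirroring how
clinical DKI protocols acquire b = 2000 regardless — with a strict mode
that rejects and reports the bound. Fitting always accepts the full
scheme. The pipeline simulates isotropic (trace-weighted) signals, so the
direction-averaged MD/MK equal the single-direction D_app/K_app; a
multi-direction extension would average fitted per-direction values.

**Rician noise.** Magnitude MR data is modeled as
sqrt((s + n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²), σ = S₀/SNR. Default
SNR 50 at b = 0, a typical body-DWI operating point. At zero signal the
magnitudes are Rayleigh with mean σ·√(π/2), the bias floor that makes
low-SNR diffusion estimates drift upward.

## Fitters

**ADC** is the negated OLS slope of ln(S) vs b with a free intercept, so
b = 0 noise does not leak into the slope; with two b-values it reduces to
the log-ratio. Fitting a bi-exponential signal with f > 0 this way always
overestimates D ("perfusion contamination"), which is why ADC > D holds
throughout.

**Segmented IVIM** (default): the conventional answer to the
ill-conditioned joint problem. Stage 1 fits ln(S) over b ≥ 200 s/mm²
(the perfusion compartment has decayed by ~e⁻¹⁵ there), giving D and the
extrapolated intercept A = (1 − f)·S₀; stage 2 takes f = 1 − A/S(0) from
the measured b = 0 point; stage 3 finds D* by a bounded scalar
minimization (Brent, xatol 10⁻¹⁰) of the full-curve residual with D, f
held. Bounds: D ∈ [10⁻⁵, 5×10⁻³], D* ∈ [D, 0.5] mm²/s, f ∈ [0, 1];
out-of-bound estimates are clipped and flagged rather than silently
accepted. The b-threshold (default 200 s/mm²) is a parameter.

**Full IVIM** refines (D, D*, f) plus the scale S₀ by trust-region
bounded least squares initialized at the segmented solution; by
construction it never increases the residual, and on clean data it
reaches the generating parameters to ~10⁻⁶ relative or better (the
segmented stage alone carries a ~10⁻⁶ relative bias in D from residual
perfusion signal at b = 200).

**DKI** is linear least squares of ln(S_b/S(0)) on (−b, b²) over the
positive-b points; a negative curvature estimate collapses to the
K_app = 0 mono-exponential refit and is flagged. With exactly three
positive b-values the solution equals the closed-form square solve.

Monte-Carlo behavior at SNR 50 matches the field's experience: D and
D_app are stable (median recovery within a few percent), f somewhat
noisier, D* by far the least stable — its relative dispersion exceeds
D's several-fold because it is identified only by the few low-b points.

## PET metrics

The lesion VOI is the fixed-fraction isocontour — voxels ≥ 40% of
SUVmax by default, the most common FDG-PET convention — restricted to the
26-connected component containing the hottest voxel (26-connectivity
keeps thin isocontour shells connected on coarse grids). MTV is voxel
count × voxel volume; TLG = SUVmean × MTV holds exactly by construction.
The threshold fraction is configurable and reported with every result.
No partial-volume correction is applied; inputs are already SUV-scaled.

## Cohort generator

The generator emulates a 73-subject two-group study (26 LVI+, 47 LVI−)
with nine biomarkers per subject, calibrated to group-level summary
statistics given as median (Q1, Q3) — or mean ± sd for MK, which is
reported that way.

**Quantile calibration.** Each median-(Q1, Q3) summary is matched by a
*quantile-spliced log-normal*: a standard-normal draw z maps to
exp(ln m + σ_lo·z) for z < 0 and exp(ln m + σ_hi·z) for z ≥ 0, with the
two half-widths set by quantile inversion of Q1 and Q3. This matches all
three configured quantiles exactly, including strongly asymmetric
summaries for which a two-parameter log-normal (median √(Q1·Q3)) can miss
the configured median by 30% or more; the symmetric-log-normal implied
median and its discrepancy are still reported on the calibration object
as an asymmetry diagnostic. MK uses a zero-truncated normal matched to
mean ± sd (truncation mass negligible at the default values).

**Conventions.** Some published parenthetical ranges are ambiguous
between quartiles and min–max; the generator reads them as quartiles by
default and offers `quantile_convention="extrema"`, which re-interprets
the flanking values as expected sample extrema at the group size
(plotting positions 1/(n+1), n/(n+1)). Read as quartiles, several
marginals become extremely wide (log-scale half-widths up to σ ≈ 6); this
is faithful to the configured numbers but produces heavier tails than a
real cohort would show.

**Reader replicates.** The two readers are modeled as equicorrelated
draws from the same calibrated marginal through a Gaussian copula with
reader–reader correlation equal to the target ICC (default 0.9, the
center of the plausible "excellent" range). This keeps each reader's
marginal — hence all pooled medians and quartiles — exactly calibrated,
and makes replicates identical at ICC 1. Because the raw-scale ICC of a
monotone transform of correlated Gaussians is attenuated for very skewed
marginals, the realized ICC sits at the copula value for moderately
skewed biomarkers and below it for the widest ones.

**Independence.** Biomarkers are drawn independently within subject (no
correlation structure is part of the calibration); a copula correlation
matrix hook exists but defaults to identity. Consequently group
separations and combined-panel AUCs in generated cohorts reflect only the
configured marginal shifts, not the between-biomarker correlations of
real tumors — pipeline results on synthetic cohorts validate the
machinery, not clinical effect sizes. Likewise the biomarker-level draws
are not forced to be consistent with the voxel-signal layer (e.g. a
subject's ADC is not derived from their drawn D, D*, f), because a
measured ADC includes perfusion contamination no single draw reproduces.
The perfusion fraction is censored at 99.9% (physical ceiling; the
calibrated quartiles sit far below it).

## Statistics layer

* **ICC:** two-way random effects, absolute agreement, single measures
  (ICC(2,1)), computed from the ANOVA mean squares; bands ≥ 0.75
  excellent / 0.60 good / 0.40 fair / < 0.40 poor. The form is the
  conventional choice for two interchangeable readers; the implementation
  is cross-checked against an independent reference in the tests.
* **Group comparison:** Shapiro–Wilk on each group at α = 0.05 routes to
  the pooled-variance Student t-test (mean ± sd summaries) or
  Mann–Whitney U (median (Q1, Q3)); constant groups route to
  Mann–Whitney with a note. The pre-test slightly perturbs the nominal
  level; simulated-null rejection stays within Monte-Carlo error of 5%.
* **ROC:** AUC by the all-pairs concordance estimator (ties ½), summed
  before division so it is bit-identical to exhaustive pair counting.
  Variance and 95% CI by DeLong's placement-value method, truncated to
  [0, 1]. The operating point maximizes Youden's J over observed score
  values, ties broken toward higher specificity (the high-specificity
  operating points typical of this literature). Direction "auto" orients
  AUC ≥ 0.5 and records the flip — diffusion parameters predict LVI
  negatively, so their cutoffs are "≤" rules.
* **DeLong comparison** of two AUCs on the same subjects via the 2×2
  placement covariance; identical or rank-identical scores give Z = 0,
  p = 1; a zero-variance difference with unequal AUCs is an explicit
  failure.
* **Logistic models:** maximum-likelihood fits (statsmodels), odds ratios
  with Wald 95% CIs. Univariate screening at p < 0.1 feeds one joint
  multivariate fit; "independent predictors" are its terms at p < 0.05.
  Perfect separation or a rank-deficient design falls back to a lightly
  ridge-penalized fit with the result flagged (separation / collinear) —
  never a silent huge OR. Combined panels (PET = SUVmax+MTV+TLG,
  IVIM = ADC+D+D*+f, DKI = MK+MD, MTV+D, ALL) are scored by the predicted
  probability, so a single-member panel reproduces that biomarker's own
  ROC exactly. No multiple-testing correction across the nine biomarkers,
  and evaluation is in-sample only — both faithful-reproduction choices;
  optimism-corrected validation is out of scope.

## Problem sizes and determinism

Monte-Carlo checks use 500 noised curves per recovery experiment, 200
cohorts for the calibration round-trip, 2000 replicates for each null
calibration, and 10⁴ bootstrap replicates for the DeLong oracle — sizes
at which the Monte-Carlo error is comfortably below the assertion
tolerances while the whole suite runs in well under a minute. Every
stochastic component takes an explicit seed (NumPy `default_rng`) and is
bit-reproducible under it; the analysis pipeline itself is deterministic.

## Known limitations

* No k-space/EPI artifacts, respiratory motion, attenuation-correction or
  partial-volume modeling; noise enters only as Rician magnitude noise.
* Biomarker independence within subject (above) caps how realistic
  combined-model performance on synthetic cohorts can be.
* The segmented IVIM fitter assumes the perfusion compartment is
  negligible above the b-threshold; for D* ≲ 10×10⁻³ mm²/s that
  assumption weakens and stage-1 D inherits perfusion bias.
* Raw-scale reader ICC is attenuated below the copula target for the most
  skewed marginals.
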