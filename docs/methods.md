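# Methods

## Statistical model

For participant *i* at visit *j*, the outcome *y_ij* is either the ordinal
clinical WMH severity staging (low/moderate/extensive, entered in the
regression as numeric 0/1/2) or the natural log of a lesion volume,
log(volume mm³ + 1). The +1 offset exists because observed regional
minima include 0 mm³ (occipital); for volumes in the thousands of mm³ it
is negligible.

The six fitted model forms combine three ingredients:

* a reference-coded group indicator (target group = 1) plus covariates —
  age, sex (male = 1), education, diagnosis dummies (MCI, AD against the
  normal-control reference), optionally diabetes, hypertension and BMI;
* a subject random intercept *u_i* ~ N(0, σ²_u) for longitudinal data,
  residuals e_ij ~ N(0, σ²_e);
* optionally a time trend (years from baseline) and a group × time
  interaction, in which case age enters fixed at its baseline value so the
  time trend is not aliased with within-person aging.

### Random-intercept estimation

The mixed model is estimated by restricted maximum likelihood, profiled to
one dimension. Writing λ = σ²_u/σ²_e and H = I + λ·blockdiag(J_i), the GLS
problem at fixed λ is solved through the per-subject shrinkage transform
ỹ_ij = y_ij − θ_i ȳ_i with θ_i = 1 − 1/√(1 + n_i λ) (identically for the
design columns), after which ordinary least squares on the transformed data
gives the GLS estimates, and

−2ℓ_R(λ) = Σ_i log(1 + n_i λ) + log|X̃ᵀX̃| + (N − p)·log σ̂²_e + const.

λ is located by a log-spaced grid scan (plus the λ = 0 boundary) refined
with bounded scalar minimization (absolute tolerance 1e-8). The boundary
estimate σ²_u = 0 is admitted and flagged; there the fit reduces exactly to
OLS, which the tests verify, along with agreement to the closed-form
balanced one-way solution and an independent REML implementation.
Fixed-effect standard errors come from the GLS information matrix;
p-values for the mixed model use the normal approximation (no Satterthwaite
degrees of freedom), recorded in the fit metadata. OLS p-values use the t
distribution with n − p degrees of freedom.

### Descriptive tests

Group descriptives are compared with Welch's unequal-variance t
(Welch–Satterthwaite degrees of freedom) for age, education and BMI, and
Pearson chi-square without continuity correction for sex, hypertension and
diabetes. Welch rather than pooled t is used because it reproduces the
published comparisons from the published per-group summaries; the pooled
statistic does not.

## Matched subsampling

Group sizes in the motivating setting differ by roughly 8:1, and the groups
differ in age, sex, education and diagnosis mix. Each bootstrap iteration
therefore draws a subsample of the reference group matched 1:1 to the
target group:

* **Exact strata** on the sex × diagnosis cells: the selected reference
  count in every cell equals the target count (hard invariant). A cell with
  too few reference candidates raises an error naming the cell; an explicit
  opt-in permits within-cell sampling with replacement, logged as a
  warning.
* **Distance matching within cells** on age and education, jointly
  standardized by the reference-pool SDs. Targets are processed in an order
  shuffled by the iteration seed; each target selects uniformly at random
  among its K nearest available candidates (default K = 25), without
  replacement.

The K-nearest randomization is deliberate. Pure greedy nearest-neighbor
selection is almost deterministic given the cohort: successive iterations
return nearly identical subsamples, the bootstrap t distribution collapses,
and its percentile intervals become vanishingly narrow — under a null
generator the 99.5% interval then excludes zero most of the time, which
defeats the purpose of resampling. With K = 25 from cells holding hundreds
to thousands of candidates, iterations genuinely resample (per-iteration t
SD ≈ 0.65 in the null scenario, close to the √((1−f)/2) value ideal random
subsampling would give at sampling fraction f) while post-match |SMD| for
age and education stays well below 0.1. K = 1 recovers greedy matching.

Per-iteration seeds derive deterministically from (master seed, iteration
index), so any subset of iterations can be reproduced in isolation.

## Aggregation and inference

Per iteration the pipeline records the group coefficient (effect size), its
t statistic and p-value (for interaction models, also the group × time
coefficient). Across iterations it reports medians and percentile CIs of
the t distribution at the 95% and 99.5% levels, using linear interpolation
between order statistics. Iterations whose fit fails are excluded and
counted; more than 5% failures aborts the run as systematically infeasible.

A contrast is called non-null when both bounds of the 99.5% interval share
a sign. This is the conservative choice among the three signals the
summaries carry (95% exclusion, 99.5% exclusion, median p), which can
disagree; all three are emitted.

The percentile interval is conditional on the realized cohort: its spread
reflects re-selection of the reference subsample but not the sampling noise
of the target group itself, so it narrows relative to full cohort-level
uncertainty as the reference pool grows. Analytically, the iteration spread
is ≈ √((1−f)/2) while the cohort-level spread of the interval's center is
≈ √((1+f)/2) (t-statistic units, f = target/pool sampling fraction); the
null exclusion rate of the 99.5% interval approaches 2/(iterations+1) as
f → 0. The null-calibration scenario therefore uses a 30:1 pool so that
nominal and actual exclusion rates agree closely. The per-cohort |median t|
under a perfect null correspondingly has expectation ≈ 0.8·√((1+f)/2) ≈
0.56–0.65 — the pipeline's null check is that the median t is *centered* at
zero across cohorts, not that each cohort's median vanishes.

### Vascular adjustment comparison

`compare_adjustment` runs the base and vascular covariate sets on identical
per-iteration matched subsamples (same derived seeds), so the difference in
median t isolates covariate adjustment from resampling noise. The result is
classified by 99.5%-flag flips: **attenuated** (non-null → null),
**revealed** (null → non-null), **unchanged** otherwise, alongside the
continuous Δ median t and Δ median effect.

## Synthetic cohorts

The generator emulates the published marginal structure of the two cohorts
the design targets — per racial/ethnic group, normal age, education
(truncated at 0 years) and BMI (truncated at 12 kg/m²) distributions,
Bernoulli sex/hypertension/diabetes, categorical NC/MCI/AD mix, at the
published group sizes — and the outcome model above with configurable
coefficients. Defaults: age +0.04 log-mm³/yr, education −0.01/yr, male
+0.10, MCI +0.30, AD +0.50, hypertension +0.25, diabetes +0.20, BMI
+0.015 per kg/m², σ_u = 0.8, σ_e = 0.6, intercept 5.0 — chosen so total
volumes fall in the published 400–140 000 mm³ range with a log-scale SD
near 1.1.

Visit counts are 1 + Poisson(mean − 1) with mean 1.87 assessments per
participant; inter-visit intervals are normal(455, 140) days floored at one
day (the published mean interval is ≈ 453–455 days) and converted to years
by /365.25. Follow-up outcomes share the participant's latent subject
intercept — carried as an in-memory `subject_intercept` column that is
never serialized — add the group-specific annual slope, and draw fresh
residuals.

Regional volumes are apportioned from the total on the log scale:
log-regional = log(weight) + log-total + N(0, 0.1²) with weights
0.58 / 0.32 / 0.055 / 0.045 (frontal / parietal / temporal / occipital),
consistent with the published regional ranges. Severity staging cuts
log(total + 1) at fixed thresholds (defaults 8.53 and 9.40, lower bound
inclusive), giving a ≈ 52 / 28 / 20 low/moderate/extensive mix under the
default parameters.

Named scenarios fix the causal structure:

* **mediation** — Black vs White at published sizes, no direct group
  effect; the whole contrast flows through the vascular prevalence gaps
  (expected unadjusted log-scale contrast ≈ 0.14).
* **suppression** — Hispanic vs non-Hispanic with strengthened vascular
  effects and a direct ethnicity effect set to exactly minus the expected
  mediated contribution, so the unadjusted contrast is null by construction
  and the adjusted contrast is clearly negative.
* **null** — two identical groups (target 120, pool 3600) with no group
  effect anywhere, for calibration checks.

### What the generator does not emulate

Site and scanner effects, spatially realistic lesion maps, non-linear
age effects, informative dropout, measurement error in the visual severity
staging, and any dependence of vascular status on time. Passing tests
therefore demonstrate that the pipeline recovers the encoded mediation /
suppression / null structures under the assumed linear model — not that the
substantive conclusions would hold in real cohort data.

## Numerical and design notes

* Severity enters linear models as numeric 0/1/2; the ordinal-to-linear
  coding matches the scale on which effect sizes are reported.
* Complete-case analysis on all model variables, with dropped-row counts
  retained in the fit metadata. Zero complete cases or constant design
  columns after filtering raise errors naming the columns.
* An exactly interpolating OLS fit (zero residual sum of squares) is
  flagged rather than raised; its t statistics are ±inf.
* Rank deficiency raises an error naming the collinear columns (QR
  diagnostic).
* Problem sizes in the validation suite: attenuation and suppression run
  20 replicate cohorts × 200 iterations at the published group sizes;
  null calibration runs 200 cohorts × 100 iterations at the 30:1 scenario
  sizes; variance-component recovery uses 500 subjects × 3 visits.
* Rendered tables round to 2 decimals; trace files keep full precision and
  are sufficient to recompute every rendered number.
* NACC-style raw vascular columns are harmonized by an any-positive /
  all-zero merge rule (HYPERT/HXHYPER/HYPERTEN; DIABET/DIABETES), with BMI
  accepted in the plausible 12–70 kg/m² range.

## Known limitations

Random slopes are not modeled (random intercept only), there is no
proportional-odds option for the ordinal outcome, no robust/sandwich
standard errors, no multiple-testing correction, and no formal mediation
decomposition — vascular contribution is assessed purely as covariate
adjustment on shared subsamples. Matching supports exactly two groups per
contrast and the two continuous matching variables are fixed (age,
education).
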