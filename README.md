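# wmhcontrast

Matched-bootstrap group contrasts of white matter hypointensity (WMH)
burden in longitudinal aging cohorts.

## The problem

White matter hypointensities — cerebrovascular lesions visible on T1-weighted
MRI — accumulate with age and predict cognitive decline. Whether their burden
differs between racial and ethnic groups, and how much of any difference is
carried by vascular risk factors (hypertension, diabetes, body mass index),
is hard to answer in observational cohorts where the groups differ in size
by an order of magnitude and in age, sex, education and diagnosis mix.

`wmhcontrast` implements the analysis such comparisons need:

1. **Matched subsampling.** Each bootstrap iteration draws a subsample of
   the larger (reference) group that matches the smaller (target) group
   exactly on the sex × diagnosis strata and closely on age and education
   (nearest-neighbor selection without replacement on jointly standardized
   covariates, randomized among the K nearest candidates so iterations
   genuinely resample).
2. **Model fits.** On each matched subsample one of six model forms is fit:

   | Model | Outcome structure | Covariates |
   |---|---|---|
   | 1 | baseline, OLS | group + age + sex + education + diagnosis |
   | 2 | longitudinal, random intercept per participant | as model 1 |
   | 3 | baseline, OLS | model 1 + diabetes + hypertension + BMI |
   | 4 | longitudinal, random intercept | as model 3 |
   | 5 | longitudinal + time trend + group × time | base covariates, baseline age |
   | 6 | longitudinal + time trend + group × time | vascular covariates |

   The outcome is either the ordinal clinical severity staging
   (low / moderate / extensive, entered as 0/1/2) or log(volume mm³ + 1)
   of total or regional (frontal / parietal / temporal / occipital) lesion
   volume. The random-intercept model is fit by profiled REML over the
   single variance ratio.
3. **Aggregation.** Across iterations (1000 by default) the pipeline
   reports the median effect size, the median t-statistic, and percentile
   confidence intervals of the t distribution at the 95% and 99.5% levels,
   with exclusion-of-zero flags.
4. **Vascular adjustment comparison.** The same matched subsamples are fit
   with and without the vascular covariates; the contrast is classified
   as *attenuated* (non-null → null), *revealed* (null → non-null, i.e.
   suppression), or *unchanged*.

Because the cohort the design targets is access-restricted, the package
ships a synthetic-cohort generator that reproduces the published marginal
structure (per-group age/education/BMI distributions, sex, hypertension,
diabetes and diagnosis mixes at the published group sizes) together with a
linear outcome model on the log-volume scale with subject random intercepts
and group-specific progression slopes. Named scenarios (`mediation`,
`suppression`, `null`) encode the causal structures of interest.

## Worked example

```python
from wmhcontrast import ModelSpec, compare_adjustment
from wmhcontrast.profiles import mediation_config
from wmhcontrast.synthetic import generate_baseline

# Quarter-scale cohort with a fully vascular-mediated Black-White contrast
cohort = generate_baseline(mediation_config(seed=1, scale=0.25))
spec = ModelSpec(outcome="severity", contrast=("Black", "White"))
cmp = compare_adjustment(cohort, spec, n_iterations=100, master_seed=0)
```

prints (via the summary fields):

```
unadjusted: median effect 0.13, median t 1.76, 95% CI (0.43, 3.31), 99.5% CI (0.30, 4.05)
adjusted:   median effect 0.02, median t 0.28, 95% CI (-1.21, 1.66), 99.5% CI (-1.28, 2.43)
classification: attenuated (delta median t = -1.48)
```

The unadjusted contrast — Black participants staged ~0.13 severity levels
higher than matched White participants — is non-null (both percentile CIs
exclude zero), and vanishes once diabetes, hypertension and BMI enter the
model: the generator put the entire group difference on the vascular paths,
and the pipeline recovers exactly that.

The same analysis is available from the shell:

```bash
wmhcontrast simulate --scenario mediation --scale 0.25 --seed 1 --out cohort.csv
wmhcontrast match cohort.csv --reference White --target Black --seed 0
wmhcontrast analyze --scenario mediation --scale 0.25 --iterations 100 --seed 0 --outdir study/
wmhcontrast report study/
```

`analyze` writes the cohort, descriptive tables with Welch-t / chi-square
group comparisons, per-model summary tables (median effect, median t, 95%
and 99.5% percentile CIs, significance markers), full-precision
per-iteration traces, and a run manifest; every rendered number is
recomputable from the traces.

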