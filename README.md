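# sleepbrain

Penalized-spline mixed models for the relationship between habitual
sleep duration and brain structure, packaged as a fully synthetic,
fully testable re-implementation of a multi-cohort lifespan analysis:

* **Longitudinal**: does the *rate of change* of a regional brain
  measure depend on sleep duration?  For scan *i* of participant *j*,

  ```
  y_ij = f(age_bl_j) + f2(sleep_j) + b1(age_bl_j)·sleep_j + b2(age_bl_j)·time_ij
         + b3(sleep_j)·time_ij + covariates_ij + u_j + e_ij
  ```

  with `f`, `f2` and the varying coefficients `b1, b2, b3` penalized
  cubic regression splines (second-derivative penalties), `u_j` a
  participant random intercept, and ML smoothing-parameter selection.
  The term of interest is `b3(sleep)·time`.

* **Cross-sectional**: `y_ij = f(age_ij, sleep_j) + covariates + u_j + e_ij`
  with `f` a tensor interaction smooth, compared against additive and
  no-sleep nested models by likelihood-ratio tests.  From the selected
  model the package estimates the *sleep duration at maximum* volume or
  thickness (minimum for ventricles), constrained to [4, 10] h, with
  uncertainty from 5,000 Monte-Carlo draws of the empirical-Bayes
  posterior of the coefficients.

* **Meta-analysis**: per-region peaks pooled by DerSimonian–Laird
  random effects with inverse-variance weights rescaled so cortex and
  subcortex contribute equally; K-means clustering of normalized
  regional curves; mega- (pooled data) vs meta- (per-cohort) comparison.

* **Mendelian randomization**: two-sample IVW on simulated GWAS summary
  statistics — instrument screen at P ≤ 1e-6, MAF ≥ 0.05, LD/distance
  pruning, allele harmonization, per-SNP F, bidirectional harness.

Everything runs on data from the built-in generator
(`sleepbrain.synthetic`), which emulates the study design — eight
cohorts whose full-size observation tallies match the published sample
table exactly (51,295 scans / 47,029 participants; 8,153 longitudinal
scans / 3,893 participants), inverted-U sleep–volume curves with a
configurable peak, site offsets, participant intercepts, an ICV column
correlated with sleep, and stratified GWAS summary statistics — so every
stage is testable without access-restricted cohort data.

## Worked example

```python
import numpy as np
from sleepbrain import synthetic as syn, crosssectional as cx, meta
from sleepbrain.registry import default_registry

reg = default_registry()
model = syn.TrueModel(h_star=6.5, sigma_resid=1.0, sigma_intercept=0.4)
df = syn.generate_cohorts(
    [syn.CohortConfig("demo", n_cross=2000, age_range=(30, 80))],
    model, seed=1, registry=reg, regions=["Hippocampus"])

fits = cx.fit_cross_models(df, "Hippocampus", reg)
pk = cx.peak_estimate(fits["additive"], reg["Hippocampus"],
                      ages=df["age"].to_numpy()[::5], n_draws=5000, seed=2)
print(f"sleep at maximum volume: {pk.h_max:.2f} h "
      f"(95% CI {pk.ci[0]:.2f}-{pk.ci[1]:.2f})")
```

prints

```
sleep at maximum volume: 6.62 h (95% CI 6.24-6.90)
```

i.e. with a true peak at 6.5 h and n = 2,000 the constrained argmax of
the fitted sleep profile lands within a tenth of an hour of the truth
and the Monte-Carlo interval covers it.

The numbered scripts under `analysis/` run the full narrative at desk
scale — `01_simulate_study.py` through `06_mendelian_randomization.py` —
writing Table-shaped TSVs under `results/`: the longitudinal battery
(no sleep–atrophy association under the generator's null), per-region
peaks with and without the ICV covariate (the uncorrected peaks shift
toward longer sleep because ICV and sleep are positively correlated),
the pooled meta-analytic peak near 6.5 h, curve clusters, and the IVW
estimate of the simulated ICV → sleep effect.  A `sleepbrain` CLI
exposes the same stages (`simulate`, `preprocess`, `fit-longitudinal`,
`fit-cross`, `meta`, `cluster`, `mr`, `run-all`).

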