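# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the open design decisions of `sleepbrain`.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spline engine

**Basis and penalty.**  Univariate smooths use cubic regression
splines: the coefficients are function values at k knots placed at
quantiles of the unique covariate values (ties resolved by
epsilon-scale offsets), the in-between curve is the natural
interpolating cubic, and the function continues linearly beyond the
boundary knots.  The penalty matrix `S = D' B^{-1} D` (the classical
banded construction) makes `beta' S beta` exactly the integrated
squared second derivative, so straight lines are unpenalized.  Default
k = 10 per univariate smooth, k = 5 per tensor margin — conventional
values that balance flexibility against desk-scale speed; self-reported
sleep arrives in 0.5-h steps, so the effective k is capped at the
number of distinct values.

**Identifiability.**  Every smooth is mean-centred over the training
rows (sum-to-zero constraint absorbed by a null-space reparametrization)
so it is identifiable next to the intercept.  Varying-coefficient terms
(`smooth(x) · by`) are centred the same way; their constant-in-x
component — the main linear effect of the `by` variable — therefore has
to be supplied as an explicit covariate (time in the change model).
This spans the same model space as leaving the terms unconstrained
while keeping the design full rank when two varying-coefficient terms
share a multiplier.

**Tensor interaction.**  The bivariate term is the row-wise Kronecker
product of marginal bases with one curvature penalty per margin,
projected orthogonal (in the constraint sense) to `[1, B_age, B_sleep]`
over the training rows.  The projection makes
interaction ⊃ additive ⊃ no-sleep an exactly nested sequence, so the
likelihood-ratio tests used for model selection are valid by
construction.

**Fitting.**  Gaussian responses only.  Penalized spline coefficients
and participant random intercepts are treated as Gaussian random
effects; smoothing parameters and the intercept-variance ratio maximize
the marginal likelihood (ML rather than REML throughout, so LRTs
between different fixed-effect structures are valid).  Writing `Dp` for
the penalized deviance at the inner penalized-least-squares optimum and
`S_b` for the total prior precision of the random block, the criterion
profiled over fixed effects and the residual variance is

```
-2 l_ML = n log(2π Dp/n) + n + log|Xr'Xr + S_b| - log|S_b| .
```

The inner solve exploits the diagonal structure of the random-intercept
block (Schur complement), so one likelihood evaluation costs
O(p²m) for p spline/fixed columns and m participants.  The outer
optimizer is L-BFGS-B on the log smoothing parameters with bounds
[-14, 18] and a convergence tolerance of 1e-6 on the log likelihood
(batteries may relax to 1e-4; the acceptance checks pass at either).
The criterion is nearly flat in the intercept-variance ratio once the
intercepts are shrunk away, and a cold start can stall on that plateau;
a method-of-moments estimate of the within/between decomposition of
ridge residuals therefore warm-starts that coordinate.  The engine's
loglik matches a dense `V = σ²I + σ_b²ZZ'` oracle to ~1e-13 in tests.

**Inference.**  `V_beta = σ̂² (X'X + S_λ)^{-1}` (empirical-Bayes
posterior covariance) with the scale `σ̂² = RSS/(n − edf_total)`; the
ML profile variance `Dp/n` is used only inside the criterion.  Smooth
terms are tested by a Wald statistic on the term's coefficient block
with pseudo-inverse rank equal to the rounded edf, referred to
F(rank, n − edf_total).  The exact reference algorithm for
estimated-df smooth tests is not pinned down by the source analysis;
this rank-rounded Wald form is a documented stand-in whose null
rejection rate calibrates within the tested band.  LRT degrees of
freedom are differences in total edf excluding the random-intercept
block; negative statistics (possible when the reduced optimizer finds a
slightly better optimum) are clamped at zero with a flag.

## The longitudinal change model

Per region: `f(age_bl) + f2(sleep) + b1(age_bl)·sleep + b2(age_bl)·time
+ b3(sleep)·time + time + sex + site + [ICV] + u_j`.  ICV enters iff
the measure is a volume and not ICV itself.  The covariate battery
refits on the complete-case subset per variant (full range, 5–9 h
restriction, +SES, +BMI, +depression, +sleep quality, per-sex), which
is why the per-variant Ns differ; sex-stratified runs drop the sex
column.  BH adjustment is applied within each region family (cortical,
subcortical) separately, per variant.

`f2(sleep)` is a deliberate addition to the varying-coefficient form:
without a main smooth of sleep, a participant-constant inverted-U sleep
effect has no home in the fixed-effect span and its unexplained
between-participant component aliases onto `b3(sleep)·time`, inflating
the change test's null rejection rate several-fold (measured ~45% at
α = 0.05 in simulation; ~5% once `f2` is included).  The term of
interest is unchanged.

Direction arrows are reported only when `b3` is effectively linear
(edf < 1.5), as the sign of the fitted curve's average slope.

## Cross-sectional peaks

The sleep profile of a fitted model is the fitted surface averaged over
the observed age distribution (up to 500 ages, equal weight per
observation); a fixed reference age is available by flag.  The
age-averaged default matches the small across-age variability of the
peak and makes the tensor average cheap
(`mean_i kron(B1(age_i), B2(h)) = kron(mean B1, B2(h))`).

The peak is the argmax (argmin for ventricle-class regions) of the
profile on a 0.01-h grid over [4, 10]; ties break toward 7 h to avoid
boundary bias.  Uncertainty comes from the argmax distribution over
5,000 draws of `N(beta_hat, V_beta)`: SE = SD of draw peaks, CI =
2.5/97.5 percentiles.  When more than half of the draws land on a range
limit the region is boundary-flagged (operationalizing "peak undefined
for monotone profiles") and excluded from pooling.

## Meta-analysis and clustering

DerSimonian–Laird between-region variance (REML-free moment estimator;
the source analysis names only "random effects"), inverse-variance
weights `1/(se² + τ²)`, then a post-hoc block rescaling so the cortical
and subcortical blocks carry equal total weight — the stated goal
("equal contribution") without a stated mechanism, so the simplest
exact-by-construction one.  Exclusions before pooling: composite
regions (total grey volume), corpus-callosum segments, ICV, and
boundary-flagged peaks.  Pooled SE is `sqrt(Σ w̃²(se²+τ²))` with
normalized weights, which reduces to `1/sqrt(Σw)` without rescaling.
Per-region Monte-Carlo draws feed the pooling only through the peak SEs
(the draw-distribution path would tie the meta-analysis to draw count;
the SE path is the conventional two-stage summary).

K-means uses scikit-learn with 50 restarts, k-means++ seeding, fixed
seed; inputs are curves normalized to percent of their own maximum, and
cluster ids are relabelled by descending size for stability.  k = 3 by
default; no choice-of-k diagnostics beyond inertia.

## Synthetic data

Regional measures are generated in within-region SD units as

```
value = age_trend(age) + curve(sleep) + rate(sleep)·time
        + site_offset + icv_loading·icv_z + sex_effect + u_j + e
```

with `curve` a quadratic with vertex `h_star` (default 6.5 h; sign
flipped for ventricles; corpus-callosum-like regions are monotone by
design, so their peaks are genuinely undefined), `age_trend` a cubic
decline (increase for ventricles) scaled by `age_slope`, `u_j ~ N(0,
sigma_intercept²)`, `e ~ N(0, sigma_resid²)`.  Sleep is drawn from a
normal centred at 7 h (SD 1.1), rounded to 0.5-h increments and clipped
to [3.5, 11] — the self-report granularity.  Region-level peak offsets
are drawn from `N(0, tau_region²)` and **centred to mean zero**, so the
ensemble-mean peak equals `h_star` exactly; with only 10–20 regions the
raw mean of free draws would wander by `tau/sqrt(k)` (~0.13 h), and
recovery tests would measure draw luck rather than estimation error.
ICV is a standardized latent correlated with the sleep latent
(`icv_sleep_corr`) plus a male offset, and loads on volumes
(`icv_loading`), so omitting the ICV covariate tilts volume–sleep
profiles toward longer sleep — the qualitative ICV confounding pattern.
SES/BMI/depression covariates are drawn with the weak sleep
correlations reported for such cohorts (|r| ≤ 0.06) and have no direct
brain effect by default, so covariate variants are null perturbations.

The shipped multi-cohort configuration reproduces the printed per-cohort
observation/participant tallies exactly at scale 1 (51,295 / 47,029 /
8,153 / 3,893).  One cohort's printed totals exceed
singles + longitudinal scans by six; the surplus is realized as repeat
scans of cross-sectional participants flagged `long_eligible=False`, so
the longitudinal subset still satisfies "≥ 2 scans per participant".

GWAS summary statistics are simulated at the SNP level only (no
genotypes): causal effects `N(0, beta_sd²)` on a configurable fraction
of SNPs, `se = 1/sqrt(2·maf·(1−maf)·N)`, outcome effects
`causal_effect × beta_true` plus sampling noise, and an optional strata
flip that negates true effects in the second stratum (negative
between-strata effect correlation).  No LD is simulated by default;
instrument pruning falls back to distance-only (any pair within the
window counts as linked), and a synthetic pairwise r² table can be
supplied where LD behaviour itself is under test.

**What passing tests do not show.**  The generator's curves are
quadratic and its noise Gaussian and homoscedastic; real morphometry
has skewed, heteroscedastic, site-dependent noise, non-quadratic sleep
relations, informative missingness and scanner drift.  Calibration and
coverage results here certify the estimation machinery under a
well-specified model, not robustness to those violations.

## Preprocessing rules

Global sleep quality = sum of the six non-duration PSQI components
(range 0–18).  The UKB-style sum score uses an explicit recode table
(`UKB_RECODE`) for the five ordinal fields; the original field codings
are not published with the field list, so the mapping is a documented,
editable convention (chronotype scored by distance from the
intermediate type).  Outliers: per region, an unpenalized cubic
regression spline fit of the measure on age (k = 10, no covariates)
defines residuals; rows with |residual| strictly greater than 4×RSE are
removed ("more than four times" → strict inequality; exactly 4×RSE
survives).  Sleep averaging replaces per-scan reports by the
participant mean; range restriction keeps the closed interval
[5, 9] h.  All filters are idempotent.

## Mendelian randomization

Defaults mirror the conventional screen: P ≤ 1e-6, MAF ≥ 0.05,
r² ≤ 0.1 within 10 kb, greedy pruning by ascending P.  Harmonization
aligns effect alleles (sign flip when the outcome reports the other
allele) and drops palindromic SNPs by default (strand is unresolvable
from summary data; a frequency-based keep flag exists).  IVW is the
fixed-effect weighted mean of Wald ratios with weights
`beta_exp²/se_out²`; its SE is `1/sqrt(Σw)`.  Note that with a P ≤ 1e-6
screen, every instrument's F = (beta/se)² exceeds ~23.9 by
construction.  Threshold sweeps (1e-5, 5e-8) are exposed as options.
No Egger/median/RAPS estimators, no LD-score regression, no polygenic
scores.

## Problem sizes and frozen conditions

* Peak-recovery study: n = 2,000 cross-sectional participants,
  `sigma_resid = 1.9` — calibrated once (single pilot grid over sigma)
  so the Monte-Carlo CI width is near the published 1.6 h, then frozen.
  200 replicates; coverage asserted within 95% ± 4.
* Meta recovery: 15 regions, `tau_region = 0.5 h`, single table of
  n = 2,000; pooled estimate within 0.15 h of 6.5.
* Longitudinal null calibration: 8 subcortical regions × 200
  replicates, 300 participants (150 longitudinal) each; BH family
  false-positive fraction ≤ 0.08.  Power: slope 0.5 SD/(h·yr),
  500 participants, 100 replicates, detection ≥ 90%.
* IVW: 500 null replicates (rejection within [0.03, 0.08]); effect 0.3
  recovered within 2 SEs.
* Mega vs meta: 50 replicates of two homogeneous 700-participant
  cohorts; median |difference| < 0.2 h.

`scripts/acceptance.py` re-runs the same analyses at slightly reduced
replicate counts (60/30/200/20) to stay within a few minutes on one
CPU; every number it reports is computed in that run.

## Known limitations

Gaussian responses only; no thin-plate splines, GCV, or smooths of 3+
variables; site enters as a fixed covariate by default (a random-site
variant is a natural extension; the source analysis is itself
inconsistent on this point, and with the generator's single offset per
cohort the fixed-effect treatment is exact); LRT p values for penalized
smooths use the edf-difference chi-square approximation, which is known
to be rough near the null; the MR module assumes non-overlapping
samples and monotone SNP effects.
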