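# Methods

This note documents the statistical procedures, the synthetic data-generating
process, the numerical conventions, and the design choices that were genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Concentration index

The canonical CI is the *convenient covariance formula*
`2·cov(y, r)/mean(y)` with the covariance taken with divisor *n*
(population convention) and `r` the midpoint fractional income rank. The
curve-integral form `1 − 2·(trapezoid area under the concentration curve)` is
kept as an independent cross-check: with the divisor-*n* convention on both
sides the two agree exactly (to floating point) on samples with untied
incomes, and this equivalence is enforced by a property test over random
inputs.

Conventions chosen where the literature leaves room:

- **Ties in income** receive the average of their positional midpoint ranks,
  which keeps the mean rank at exactly 0.5. With ties, the curve form and the
  covariance form can differ slightly (the curve depends on the order in
  which tied rows are stacked); the covariance form is authoritative.
- **Weights.** Computations are unweighted by default (no survey weights are
  modelled); weighted fractional ranks are available.
- **Negative outcome values** (possible for log expenses below one currency
  unit) are permitted with a warning; the bound |CI| ≤ 1 is only guaranteed
  for non-negative outcomes.
- **Bounded outcomes.** For binary outcomes the plain CI is used throughout —
  no Erreygers/Wagstaff normalization — matching the practice of the analysis
  this package mirrors.

## Time-varying DID

`fit_did` is OLS of the outcome on the treatment indicator, substantive
covariates, and city + year dummies. Binary outcomes are deliberately fit as
linear probability models: the Wagstaff decomposition needs linear
coefficients, and the LPM keeps estimation and decomposition internally
consistent. Standard errors are HC1-robust by default with city clustering
behind a flag.

Identification guards: a requested factor that is constant on the estimation
sample, or that lies in the span of the remaining design (the typical case
being a treatment indicator with no within-city switch, absorbed by city
dummies), raises an explicit "inestimable" error; redundant fixed-effect
dummies are dropped with a warning instead. Collinearity is detected by
pivoted QR and attributed by the SVD null space.

Expense outcomes (`lnoutself`, `lnhosself`) are estimated conditional on use:
rows with a missing expense (non-users) are dropped, which is also how the
reported sample sizes of the mirrored analysis behave.

Income-quartile heterogeneity refits the same specification within quartiles
cut at the pooled sample quantiles of log income; a value exactly at a
boundary falls in the lower quartile (right-closed bins).

## Wagstaff decomposition

Contributions are computed as `2·ρ_k·cov(x_k, r)/ȳ`, which equals
`η_k·CI(x_k)` whenever the factor mean is nonzero but remains well-defined
otherwise. The residual is the generalized CI of `y − Σ ρ_k x_k` scaled by
the **outcome mean** — the scaling under which the additive identity closes
exactly (asserted to 1e-10 in tests); a mean-income scaling of the residual,
which sometimes appears in print, does not close and is not used. Fixed-effect
dummies default into the residual so that the factor table contains only
substantive covariates; `include_fixed_effects=True` lists them instead, and
either choice leaves the total CI and the identity untouched.

Per-wave decomposition tables refit the regression within each wave. Within a
single wave the treatment is constant inside each city, so city fixed effects
would absorb it; the per-wave fits therefore use the plain covariate
regression without fixed effects.

## Between-group split

Within-group CIs re-rank income **inside each subsample**; the intergroup
term is defined as the residual `total − Σ (N_g/N)·CI_g`, which makes the
identity hold by construction and is the reading under which the published
between-group numbers reproduce. The same residual split is applied to the
treatment's own CI and to its contribution rate. Per-group contribution
rates come from full per-group regression + decomposition refits; groups on
which the regression is inestimable are flagged with NaN. Overlap terms from
the income-inequality literature are out of scope.

## Oaxaca change decomposition

The default weighting pairs the **lagged elasticity** with the CI change and
the **current CI** with the elasticity change; this is an exact algebraic
identity (`Δ(η·CI) = η_{t−1}ΔCI + CI_tΔη`) and the variant that reproduces
the published worked-example cells. The symmetric alternative (current η,
lagged CI) sums to the same total and is available via `weighting=`.

## Robustness procedures

**PSM-DID.** The propensity score is an unpenalized logit of the treatment on
the standardized covariate set (the matched analysis never states its exact
specification; this is the package's assumption, recorded as such). Rows
outside the common support — the overlap of the treated and control score
ranges — are trimmed; each treated unit is matched 1-NN with replacement
(optional caliper); the DID is refit on the trimmed sample. Refitting on the
trimmed rather than the matched-pairs sample reproduces the characteristic
small drop in n of this design; the matched pairs are returned for balance
diagnostics, and nearest-neighbor correctness is tested against exhaustive
search.

**Placebo test.** Coverage is reassigned at random to individuals, preserving
the treated share within each wave (default), or, behind a flag, by permuting
adoption years across cities. Since only the treatment column changes between
replicates, all other regressors are partialled out once (QR) and each
replicate's coefficient is a single projected inner product — numerically
identical to a full refit, which a test verifies. The kernel density exported
for plotting uses a Gaussian kernel with Silverman bandwidth (cosmetic
choice).

## Synthetic data-generating process

The generator emulates the restricted three-wave survey the analysis mirrors:

- **Nesting and income.** Individuals are assigned uniformly to cities. Log
  per-capita household income is `8.642 + u_c + a_i + e_it` with city effect
  s.d. 0.45 (+0.20 for eastern cities), persistent individual s.d. 1.20, and
  wave-level s.d. 0.80 — totalling ≈ 1.53, near the survey's printed 1.59.
- **Staggered, wealth-correlated adoption.** Each city draws one uniform
  v_c (stratified across cities so realized coverage tracks targets tightly)
  and adopts by wave w iff `v_c < target_w·(k+1)·p_c^k`, with p_c the city
  wealth percentile and k = 1 by default. This yields absorbing adoption,
  per-wave population coverage calibrated to 0.0985 / 0.1479 / 0.2717, and a
  pro-rich coverage CI ≈ 0.10–0.12. Setting k = 0 removes the wealth gradient.
- **Covariates** match the survey's printed means (gender 0.473, married
  0.831, rural 0.890, household size 3.96, pension 0.521, sanitation 0.849,
  east 0.353, education categories 0.171/0.628/0.124/0.037/0.001), with
  education, sanitation, pension and (negatively) rural status linked to the
  individual's income percentile so their CIs are non-trivial.
- **Binary outcomes** are Bernoulli draws from a **clipped linear
  probability** index: true coefficients (defaults in the neighbourhood of
  published LPM estimates, e.g. a +0.0243 treatment effect on good health)
  plus small city and year effects, with the intercept calibrated so the
  sample prevalence hits the target (healthy 0.557, outpatient 0.087,
  hospitalization 0.081). A uniform latent threshold rather than a Gaussian
  one is intentional: it makes the two-way FE linear probability model
  correctly specified, so coefficient-recovery and null-calibration tests
  are meaningful. Clipping to [0.001, 0.999] affects a negligible tail.
- **Expenses** are drawn only for users, log-normal conditional on
  utilization, with the treatment shifting the log-mean by the configured
  (negative) effect and the intercept calibrated to the conditional means
  (4.246 / 6.836). An optional treatment-by-income-percentile interaction
  builds heterogeneous-effect scenarios for the quartile tests.
- **Incomes are emitted already deflated**; no further deflation step exists
  in the pipeline.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: survey sampling weights and design effects, geographic
structure beyond city labels, measurement error in self-rated health,
serial correlation in outcomes beyond what the city/individual effects
induce, and a *rising* coverage CI across waves (with a fixed wealth
gradient, expanding coverage mildly dilutes its own CI over time, whereas
the mirrored rollout became more pro-rich as it expanded).

## Problem sizes and seeds

Default generator scale is 20,000 individuals × 3 waves in 60 cities; the
mirrored study's 34,134 observations are reachable by config but not needed.
The repeated-seed calibration suites (DID recovery coverage, 5% null
rejection rate) run 200 seeds at 1,500 individuals × 3 waves in 24–30
cities — the package's chosen scale for tight Monte-Carlo bands at modest
cost. All randomness flows from explicit integer seeds; identical config and
seed reproduce panels byte-for-byte.

## Known limitations

- Staggered-adoption two-way FE DID is used as-is; heterogeneity-robust
  estimators (Callaway–Sant'Anna and kin) are deliberately out of scope.
- The plain CI on binary outcomes is not normalized for their bounds.
- PSM standard errors are not matching-adjusted (no bootstrap).
- The between-group split uses population shares only (no income-share
  weighting or overlap term).
- City-level treatment coding: an individual is treated iff their city has
  adopted, so within-city non-compliance is not modelled.
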