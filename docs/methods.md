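# Methods

`childhte` estimates the effect of resident basic medical insurance
enrollment on child anthropometric outcomes — weight-for-height (WHZ),
weight-for-age (WAZ) and height-for-age (HAZ) z-scores for preschool
children (ages 0–5) and BMI for school-age children (6–16) — and, beyond the
average effect, how that effect varies with family circumstances. Because
the underlying survey microdata are access-restricted, the package ships a
synthetic cohort generator with known ground truth; every estimator is
validated by parameter recovery against that truth.

## Causal model and estimands

Each child has potential outcomes `y1` (enrolled) and `y0` (not enrolled);
the individual effect is `tau_i = y1_i - y0_i`. Under the conditional
independence assumption (enrollment is as-good-as-random given the observed
covariates), two families of estimands are targeted:

* **ATT** — `E[tau | W = 1]`, estimated by propensity-score matching;
* **CATE** — `tau(x) = E[y1 - y0 | X = x]`, estimated by an honest causal
  forest; the per-unit forest predictions are called CITEs, and subgroup
  effects are CITE averages (CATC when averaged over a subgroup's control
  units, the reporting convention used for the uninsured).

## Propensity-score matching

The enrollment propensity `P(W = 1 | x)` is a maximum-likelihood logit in
the child, mother and household covariates, fitted by IRLS (convergence when
the largest coefficient step falls below 1e-8, at most 100 iterations;
perfect separation and rank-deficient designs raise explicit errors).
Matching runs inside the common-support interval
`[max(min-score per arm), min(max-score per arm)]`:

* nearest-neighbor with k = 1 or k = 4, each matched control weighted 1/k,
  ties broken toward the lowest record index, with replacement by default —
  controls are only ~14% of the cohort, so matching without replacement
  would exhaust the pool;
* kernel weighting over all in-support controls, Epanechnikov
  `K(u) = 0.75 (1 - u^2) 1{|u| < 1}` with bandwidth 0.06 by default
  (Gaussian available); treated units with zero kernel mass are dropped and
  counted.

`ATT = mean over treated of (Y_i - sum_j w_ij Y_j)`. Standard errors come
from a nonparametric bootstrap (B = 200 by default) that re-fits the
propensity model and re-matches inside every resample. Balance diagnostics
report standardized mean differences before/after matching, scaled by the
pre-matching pooled SD in both cases so the columns are comparable.

## Honest causal forest

Nuisance functions `m(x) = E[Y|x]` and `p(x) = E[W|x]` are random-forest
regressions whose out-of-bag predictions act as cross-fitting; propensity
predictions are clipped to [0.01, 0.99]. With residuals
`y_res = Y - m_hat`, `w_res = W - p_hat`, the local (R-learner) effect over
a neighborhood is

    tau_hat = sum(w_res * y_res) / sum(w_res^2),

which is first-order insensitive to nuisance estimation error. Trees are
honest: each tree's half-subsample (drawn without replacement; stratified by
arm) is split 50/50 into a structure half that chooses splits and an
estimation half that supplies every leaf's effect, so no outcome is used both
to place a split and to estimate the effect behind it. Every leaf must keep
at least `min_leaf = 5` treated and 5 control units in *both* halves, which
guarantees each leaf can form its own counterfactual.

**Split criterion.** Candidate splits maximize the between-child effect
heterogeneity. The naive criterion `n_L tau_L^2 + n_R tau_R^2` is upward
biased by exactly `n_child Var(tau_hat_child)` per child, which makes greedy
search favor covariates with many candidate thresholds — in experiments
under the default ~86%-treated confounded design this let spurious splits on
continuous covariates crowd out a true binary effect modifier and attenuated
recovered subgroup contrasts by roughly half. The default criterion
therefore subtracts an estimate of that inflation,

    gain = sum over children of n (tau_hat^2 - Var_hat(tau_hat)),
    Var_hat(tau_hat) = sum (c_i - tau_hat d_i)^2 / (sum d_i)^2,

with `c_i = w_res_i y_res_i`, `d_i = w_res_i^2` (the parent is scored the
same way, and splitting stops when no admissible split improves the gain
beyond a relative tolerance of 1e-10). `split_penalty = 0` restores the
uncorrected criterion. `mtry = ceil(sqrt(p))` covariates are drawn per node;
thresholds are midpoints of consecutive distinct structure-half values.

**Forest weights and CITEs.** For a query point x, `alpha_i(x)` averages
over trees the indicator that record i lies in x's leaf estimation set,
normalized by the set's size; the forest CATE is the alpha-weighted local
estimator. The fast prediction path aggregates per-leaf sufficient
statistics and is exactly equal to the explicit-weights evaluation (tested
to 1e-10).

**Two-stage screening.** Stage 1 grows a forest on all (one-hot encoded)
covariates; covariates are ranked by depth-discounted split frequency
(contribution `2^-depth`, root depth 1, depths beyond 4 ignored — one of
several defensible conventions, normalized to sum to one) and those above
the mean importance are retained. Stage 2 regrows the forest on the
retained covariates only, *reusing the stage-1 nuisances*: the nuisances
adjust for confounding and must keep the full covariate set even when the
trees do not. An optional small grid search over `(min_leaf, mtry)` scored
by the R-learner loss `mean((y_res - tau_hat(x) w_res)^2)` stands in for the
original procedure's tuning step.

**Heterogeneity verdict.** The empirical 2.5th–97.5th percentile interval of
the CITE distribution is reported to three decimals. By the default
(`sign-varying`) rule an interval straddling zero is labelled
"heterogeneous (sign-varying)" — reading the spread as evidence that
per-unit effects change sign; the `conventional` rule reads the same
interval as an effect indistinguishable from zero. Both readings are
offered because the field's reporting conventions differ; the default
mirrors the reporting style this pipeline replicates.

Subgroup SEs are the naive `sd/sqrt(n)` of the averaged CITEs — documented
as *not* a calibrated forest variance (asymptotic forest confidence
intervals via the infinitesimal jackknife are out of scope).

## Synthetic cohort generator

The generator emulates the structure of the 2018 rural-child insurance
sample: 5552 children, ~85.7% enrolled (4760/792), preschool share 0.363
(the two cohort analyses use 2015 and 3537 records respectively). Covariate
marginals, chosen to match the published descriptive moments:

| covariate | default law |
|---|---|
| child age | uniform integers on the cohort range (0–5 / 6–16) |
| mother age | child age + Normal(27, 5), clipped to [16, 55] |
| mother education (1–7) | categorical weighted toward primary/junior-high (mean ≈ 2.9) |
| log income per capita | Normal(9.0, 0.95) |
| urban residence | Bernoulli(0.35) |
| region (E/C/W) | multinomial (0.30, 0.35, 0.35) |
| wealth quintile | within-sample quintile of log income + Normal(0, 0.3) jitter |

The wealth-quintile rule is a documented stand-in: how the original study
built its quintiles (income vs. a wealth index) is not stated. Enrollment is
a Bernoulli draw from a logit whose slopes load negatively on income and
urban residence and positively on mother's and child's age (directions read
from the published group contrasts); the intercept (4.240) was calibrated
once so the default mix yields an enrollment share within 0.01 of 0.857 at
large n. Outcomes follow the partially linear model
`Y = f(x) + W tau(x) + eps` with `f` linear in mother's education, log
income and child age (BMI uses a level-shifted `f` with mean near 18.3 and
noise SD 3.0, near the published dispersion), `eps ~ Normal(0, 0.8)` for
z-score outcomes (the published outcome SDs are 0.77–1.01), and `tau(x)`
built from a baseline plus named binary-modifier increments (rural, low
mother education, ...) and centered continuous slopes. Potential outcomes
satisfy `Y = W y1 + (1 - W) y0` bit-exactly. Each stage (covariates,
treatment, noise) uses its own RNG stream derived from the master seed, so
stages are independently reproducible and a single seed determines every
number downstream.

What the generator does **not** model: survey weights, attrition, household
clustering, panel structure, raw height/weight measurement (outcomes are
taken as given z-scores/BMI), heavy-tailed noise, and unobserved
confounding. Passing recovery tests therefore demonstrate internal validity
of the estimators under selection-on-observables, not robustness to
violations of it.

## Problem sizes, tolerances and what the tests show

Desk-scale defaults keep a full run in minutes on one CPU: forests use
100–300 trees (the original procedure's 1000/3000 are available through
configuration), recovery experiments use n = 2000–4000 with replicate
averaging over a fixed seed set.

Monte Carlo context for the recovery tolerances: under the default
conditions (n = 4000, noise SD 0.8, ~86% treated, rural increment 0.4) even
the *oracle* local estimator using the true nuisances recovers the subgroup
contrast with SD ≈ 0.08 across cohort draws, so the 0.15 recovery tolerance
sits at about two oracle SDs; the constant-effect tolerance of 0.1 is
similarly ~2 SD for the kernel-matching ATT. Recovery tests average 2–3
replicates at fixed canonical seeds to keep the checks inside those bands
without enlarging the problem sizes.

Numerical choices: propensity probabilities clipped at 1e-10 inside IRLS;
forest prediction raises if the weighted treatment-residual mass at a query
point falls below 1e-12; matching ties break toward the lowest record
index; the median-split profile assigns the median record to the lower
half; degenerate inputs (constant treatment, empty support intersection,
subgroups without controls, constant CITEs) raise explicit errors rather
than returning silent NaNs.

## Known limitations

* Subgroup and CITE-interval uncertainty is descriptive, not inferential
  (no calibrated forest variance).
* The logit enters ordinal covariates (education, region, wealth) as
  integers — matching the source coding — while the forest one-hot encodes
  them; the two stages intentionally differ.
* Bootstrap SEs re-estimate everything inside each resample and scale
  accordingly; at B = 200 on the full cohort the matching stage dominates
  run time, so the orchestrated pipeline defaults to B = 50.
* Heterogeneity recovery degrades gracefully but measurably when the
  realized contrast in a particular cohort draw is weak; see the Monte
  Carlo context above.
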