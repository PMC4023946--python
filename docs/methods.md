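# Methods

## Scope and data model

`ssiml` analyses cohorts of surgical procedures with a binary
surgical-site-infection (SSI) outcome observed within a surveillance
window, organized hierarchically: patients within surgical wards within
hospitals. A cohort is a flat table (one row per procedure) with hospital
and ward identifiers, the outcome, ten binary patient covariates
(female gender, age ≥ 65, ASA score > 2, preoperative stay ≥ 48 h,
Altemeier wound class > 2, endoscopic surgery, emergency surgery,
ambulatory surgery, follow-up ≥ 15 days, surgery duration above the
procedure-specific 75th percentile) and a six-category procedure type
(gastrointestinal as reference). Binary columns use pandas' nullable
integer dtype; the CSV dialect writes missing values as empty fields and
round-trips exactly.

## The three models

1. **Empty model** — intercept plus random intercepts at the ward and
   (optionally) hospital level; used to partition outcome variance across
   levels before covariates enter. The hospital level is retained only if
   its variance-component test (below) is significant at 0.05.
2. **Random-intercept model** — patient covariates with common slopes and
   a ward random intercept `u_0j ~ N(0, s00)`.
3. **Random-coefficient model** — additionally lets the follow-up ≥ 15 d
   effect vary by ward: `(u_0j, u_15j) ~ N2(0, Sigma)`. The effective ward
   variance is then stratum-specific: `s00` for short follow-up,
   `s00 + 2 s01 + s11` for long follow-up.

Candidate covariates can be pre-selected by a liberal univariate screen
(one ward-random-intercept fit per candidate, retain when the two-sided
posterior tail probability is below 0.20; any non-reference level suffices
for procedure type).

## Estimation

Fitting is Bayesian via Metropolis-within-Gibbs:

* **Fixed effects**: one joint random-walk proposal shaped by the Cholesky
  factor of the inverse Fisher information from an internal IRLS logistic
  fit (which also initializes the chain), scale adapted toward ~23%
  acceptance.
* **Cluster effects**: per-cluster random-walk proposals, accepted or
  rejected independently for every cluster in vectorized form (the
  likelihood factorizes over clusters given everything else). Scalar
  blocks target ~44% acceptance, bivariate ward blocks ~35%, each with its
  own adapted scale.
* **Variance components**: conjugate Gibbs updates — inverse-gamma for
  scalar variances, inverse-Wishart for the 2×2 ward covariance (which
  keeps every stored draw positive semidefinite by construction).
* **Recentering and rescaling moves**: with ~1 infection per ward the
  centered parameterization couples the effects and their variance so
  strongly that the variance trace still drifts after tens of thousands of
  sweeps. Two auxiliary Metropolis moves remove this: a common shift of
  all cluster effects absorbed into the corresponding fixed effect(s)
  (likelihood-invariant; accepted on the prior ratio alone) and a joint
  rescaling of effects and (co)variance with the exact Jacobian and prior
  correction. With them, posterior traces are stationary within ~2000
  burn-in sweeps on the cohort sizes used here.

Priors default to the diffuse conventions of mainstream multilevel
software: Normal(0, 1e6) per fixed effect, inverse-gamma(0.001, 0.001) for
scalar variances, inverse-Wishart with identity scale and 2 degrees of
freedom for the ward covariance; all configurable via `PriorSpec`. Default
chain settings are 5000 burn-in, 50000 total sweeps, thinning 10;
adaptation runs during burn-in only, so the retained chain is a fixed
Markov kernel. The recovery experiments and acceptance script use reduced
chains (2000 burn-in, 10000 sweeps, 800 stored draws), which the
stationarity of the traces supports. Summaries report posterior means and
SDs, exponentiated means as odds ratios, 2.5/97.5 percentile intervals,
tail-based two-sided p-values floored at 2/n_draws, plus effective sample
size and a split-chain convergence statistic; non-convergence produces a
warning on the summary, never a silent pass. Probabilities inside the
standalone log-likelihood are clamped at 1e-12.

## Level-variance test

Whether a random level contributes (e.g. the hospital level in the empty
model) is tested by a likelihood-ratio statistic between nested empty
models whose marginal likelihoods are maximized under a Laplace
approximation (inner Newton mode-finding per cluster block; the joint
log-determinant uses a Schur complement that stays diagonal because wards
nest in hospitals). Since the null value of a variance lies on the
boundary of its space, the statistic is referred to the 50:50 mixture of a
point mass at zero and chi-square(1). Laplace approximations underestimate
variance point estimates for rare binary outcomes, but the bias largely
cancels in the nested difference; the test's type-I error is checked
empirically (≤ 10% at nominal 5% over 100 null replicates) in the suite.

## Median odds ratio

`MOR = exp(sqrt(2 sigma^2) * Phi^{-1}(0.75))` — the median of the odds
ratio between the higher- and lower-risk member of a randomly drawn pair
of wards; 1 under homogeneity, invariant to outcome prevalence. The point
estimate applies the formula to the posterior *mean* of the (stratum)
variance — the posterior median is available as an option — and the
interval applies it to the 2.5/97.5 variance percentiles (monotonicity
makes transformation and percentile-taking commute). The interval is
labeled 95%, which is what those percentiles define. Tests verify the
formula against a direct Monte-Carlo oracle (median of `exp(|u1 - u2|)`
over sampled pairs) to within 1%.

The inverse formula `sigma^2 = (ln MOR / 0.67449)^2 / 2` is exposed as
`mor_to_variance`; the generator defaults were derived with it so that
simulated cohorts correspond to published MOR values (1.343 ↔ 3.02,
1.795 ↔ 3.59, 4.112 ↔ 6.92, 1.582 ↔ 3.32).

## Synthetic cohorts

The generator emulates the structure of a large national surveillance
extract: ~1% overall infection risk, the eleven covariates drawn at their
observed marginal prevalences, generating log-odds equal to the logs of
published adjusted odds ratios, bivariate ward effects whose stratum
variances reproduce the published stratum MORs, and an optional hospital
variance (0 by default, as the hospital level contributed nothing in the
emulated analysis). Ward sizes are uniform integers over a configurable
range (default 10–250, mean ≈ 124 consistent with the ward-size filter and
the emulated cohort's mean). Optional per-covariate missingness supports
testing the sparse-variable discard rule.

Deliberate simplifications, and what they imply for the tests:

* **Covariates are mutually independent.** Real surveillance covariates
  are strongly correlated (ophthalmic procedures are short, ambulatory and
  low-ASA, for example). Independence makes the covariates *jointly more
  informative* than in real data, so discrimination measures come out
  higher than published values: the covariates-only AUC is ~0.82–0.84
  rather than 0.73, and the ward-informed AUC ~0.93–0.95 rather than 0.84
  (the generating linear predictor itself scores ~0.94). Passing
  coefficient- and MOR-recovery tests therefore demonstrates correct
  estimation, not that real-data discrimination would match.
* **Ward effects are independent of case-mix**, whereas real wards' risk
  profiles correlate with their specialties.
* No infection-timing, infection-depth or mortality structure.
* The generating intercept is calibrated by 1-D root-finding on a
  Monte-Carlo estimate of the marginal prevalence (the documented default
  −4.8504 gives ~1% under the default configuration); no baseline odds is
  assumed.
* The slope-variance/covariance split of the default ward covariance is
  underdetermined by the two stratum variances alone; the default fixes
  the slope variance at 1.0, giving covariance −1.765 (correlation −0.87).

## Preparation rules

* Ward-size filter: keep wards with ≥ 10 patients (idempotent, order
  preserving).
* Hospital subsampling: draw `round(f × H)` whole hospitals without
  replacement (half-up rounding), deterministic per seed; sample and
  remainder partition the cohort exactly.
* Sparse-covariate discard: drop covariates missing in **strictly more**
  than 10% of records; exactly 10% is retained.
* Duration dichotomization: within-procedure-type 75th percentile with
  linear interpolation between order statistics (the quantile and its
  definition are configurable), computed on the analysed cohort itself;
  strictly greater durations are flagged; missing durations propagate.
* Follow-up dichotomization at ≥ 15 days.
* Residual missingness is handled by complete-case analysis per fitted
  model; no imputation.

## Validation

Applying a fit to a cohort requires a **ward-effect policy**: `zero`
(case-mix only), `training` (posterior means for wards seen in training,
zero otherwise), or `empirical_bayes` (default) — per-ward posterior modes
re-estimated on the evaluation cohort at fixed coefficients and ward
covariance, by a damped (backtracking) Newton iteration on the penalized
per-ward log-likelihood, with a ridge pseudo-inverse for singular
covariances. Effects shrink to zero as ward data vanish or the covariance
shrinks. The default reflects surveillance practice: a ward being scored
has its own recent outcomes available, and without any ward information a
hierarchical model cannot out-discriminate its single-level counterpart.
Note that empirical-Bayes effects estimated on the evaluation cohort reuse
its outcomes, so the resulting AUC is an in-sample quantity with respect
to the ward level (it can exceed the true-parameter AUC slightly); all
three policies are exposed so users can bracket the honest range.

AUC is the midrank Mann–Whitney estimator (ties count ½), verified against
an exhaustive pair-count oracle; ROC curves are computed at every distinct
threshold and their trapezoidal area equals the midrank estimator exactly.
Single-AUC standard errors use the Hanley–McNeil (1982) formula with
`Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`. Paired comparisons default to the
placement-value (DeLong) covariance construction; a Hanley–McNeil-style
engine combines the 1982 SEs with an AUC correlation supplied by the user
or approximated by the average within-class Pearson correlation of the
paired scores (the published lookup table for that correlation is coarse,
so the engine accepts an explicit `r` for exact legacy workflows).

The SIR of a unit is observed infections over the sum of predicted
probabilities; for a maximum-likelihood single-level fit evaluated on its
own training cohort the overall SIR is exactly 1 (the score equation),
which the suite asserts.

## Problem sizes and runtime choices

Recovery experiments use 200 wards × 100 patients (20,000 records), the
scale at which the emulated analysis operated per ward, with reduced
chains (2000/10000/10). At ~1% prevalence this is ~1–2 infections per
ward, so ward-variance estimates are intrinsically noisy: across seeds the
recovered variance scatters by roughly ±15% even for a correct sampler
(cross-checked against lme4/glmmTMB marginal-likelihood fits during
development). The validation experiment uses 150-ward training and
validation cohorts. The pipeline's report rounds odds ratios and MORs to
two decimals.

## Known limitations

* One random slope at most; no crossed random effects; no frequentist
  REML/quadrature fitting.
* The univariate screen refits a short MCMC chain per candidate; it is the
  slowest part of the full pipeline at default settings.
* The Laplace-based level test is a point approximation; its p-values are
  calibrated empirically only near the null sizes used in the suite.
* Calibration metrics (Brier, Hosmer–Lemeshow) are out of scope; the
  package measures discrimination and standardized counts only.
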