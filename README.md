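# ssiml — multilevel modeling of surgical-site-infection risk

`ssiml` is a toolkit for hospital-infection surveillance statisticians who
want to model surgical site infection (SSI) risk with the hierarchical
structure of surveillance data — patients nested in surgical wards nested in
hospitals — rather than with a patient-covariates-only logistic regression.

It implements, as a tested and reusable package:

* a **synthetic cohort generator** emulating a large national SSI
  surveillance extract (rare binary outcome ≈ 1%, eleven patient covariates
  at realistic marginal prevalences, ward-level random intercepts and a
  random follow-up coefficient, optional hospital level), since real
  surveillance extracts are confidential;
* **cohort preparation** rules: minimum ward size, whole-hospital random
  subsampling, sparse-covariate discard, within-procedure duration
  dichotomization;
* **Bayesian 2- and 3-level logistic regression** fitted by an adaptive
  Metropolis-within-Gibbs sampler — the empty variance-partition model, the
  random-intercept model and the random-coefficient model;
* the **median odds ratio (MOR)** heterogeneity statistic with credibility
  intervals and stratum-specific variants for random-coefficient fits;
* **validation tools**: predicted probabilities under several ward-effect
  policies (including empirical-Bayes effects for new wards), the
  standardized infection ratio (SIR), and paired ROC/AUC comparison
  (DeLong placement values, with a Hanley–McNeil-style alternative).

## The model

For patient *i* in ward *j*, the random-coefficient model is

    y_ij ~ Bernoulli(pi_ij)
    logit(pi_ij) = beta0 + beta' x_ij + u_0j + u_15j f_ij
    (u_0j, u_15j) ~ N2(0, [[s00, s01], [s01, s11]])

with `x_ij` the patient covariates and `f_ij` the indicator of a
post-surgery follow-up of at least 15 days. Between-ward heterogeneity is
summarized by the median odds ratio

    MOR = exp( sqrt(2 sigma^2) * Phi^-1(0.75) ),

the median odds ratio between the higher- and lower-risk member of a random
pair of wards; `sigma^2` is `s00` for the short-follow-up stratum and
`s00 + 2 s01 + s11` for the long-follow-up stratum. The SIR of a ward is
its observed infection count divided by the sum of its predicted
probabilities.

Priors are the diffuse conventions of mainstream multilevel software
(Normal(0, 1e6) fixed effects, inverse-gamma(0.001, 0.001) scalar
variances, inverse-Wishart(identity, df 2) ward covariance). The sampler
combines vectorized per-cluster random-walk Metropolis updates, conjugate
Gibbs draws for variance components, and recentering/rescaling moves that
keep the chain mixing even at one infection per ward.

## Worked example

```python
from dataclasses import replace
from ssiml import default_config, generate_cohort, stratified_mor
from ssiml.preprocess import filter_small_wards
from ssiml.hierarchical_model import fit_model2_intercept, McmcSettings

cfg = replace(default_config(seed=42),
              n_hospitals=40, wards_per_hospital=5, patients_per_ward=100)
cohort = filter_small_wards(generate_cohort(cfg), min_n=10)
print(f"{cohort.n_patients} patients, {cohort.n_wards} wards, "
      f"{cohort.df['ssi'].sum()} infections ({100*cohort.df['ssi'].mean():.1f}%)")

draws, summary = fit_model2_intercept(
    cohort, mcmc=McmcSettings(burn_in=2000, iterations=10000, thin=10, seed=1))
tab = summary.coefficients
for name in ("asa_gt2", "duration_gt_p75", "ambulatory"):
    row = tab[tab.coefficient == name].iloc[0]
    print(f"{name:16s} OR {row['or']:.2f} "
          f"({row['or_lower']:.2f} to {row['or_upper']:.2f})  p={row['p']:.3g}")
mor = stratified_mor(draws)[0]
print(f"MOR {mor.mor:.2f} (95% CI {mor.lower:.2f} to {mor.upper:.2f})")
```

prints

```
20000 patients, 200 wards, 218 infections (1.1%)
asa_gt2          OR 1.82 (1.28 to 2.60)  p=0.0025
duration_gt_p75  OR 2.23 (1.57 to 3.22)  p=0.0025
ambulatory       OR 0.26 (0.15 to 0.40)  p=0.0025
MOR 6.77 (95% CI 4.57 to 11.10)
```

Each odds ratio is the exponentiated posterior-mean log-odds of its
covariate (ASA > 2 raises the infection odds by ~80% here; ambulatory
surgery lowers them), and the MOR of 6.77 says that moving the median
patient from a lower-risk to a higher-risk ward multiplies their odds of a
reported infection by ~6.8 even after case-mix adjustment — in this cohort
the generating ward covariance is the package default, whose overall
effective variance sits between its two stratum values, and a
random-intercept model pools the two strata. The Bayesian p-values are
floored at 2/n_draws (800 stored draws here).

A full pipeline (generate → prepare → level selection → screening →
models 1–3 → MOR table → held-out ROC/SIR validation) is available as
`ssiml run --config pipeline.yaml`, and each stage separately as
`ssiml generate | prep | fit | mor | validate`.

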