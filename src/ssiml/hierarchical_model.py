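"""Bayesian 2- and 3-level logistic regression fitted by MCMC.

The models are the classical hierarchy of multilevel logistic regressions
for a rare binary outcome observed on patients nested in wards nested in
hospitals:

* **empty model** — intercept plus random intercepts at the ward (and
  optionally hospital) level, used to partition outcome variance across
  levels before any covariate enters;
* **random-intercept model** — patient-level covariates with a common
  slope vector and a ward random intercept;
* **random-coefficient model** — additionally lets one covariate effect
  (here the follow-up >= 15 days indicator) vary between wards, with a
  bivariate normal distribution for the ward (intercept, slope) pair.

Estimation is Metropolis-within-Gibbs: adaptive random-walk Metropolis for
the fixed effects (one joint proposal shaped by the ML Fisher covariance)
and for each cluster-effect block (all blocks proposed and accepted
independently in vectorized form, since the likelihood factorizes over
clusters given the remaining parameters), with conjugate Gibbs draws for
the variance components (inverse-gamma for scalar variances,
inverse-Wishart for the 2x2 ward covariance).  Proposal scales adapt during
burn-in only, so the post-burn-in chain is a fixed Markov kernel.

Priors default to the diffuse conventions of mainstream multilevel
software: Normal(0, 1e6) on each fixed effect, inverse-gamma(0.001, 0.001)
on scalar variances, inverse-Wishart(identity, df=2) on the ward
covariance.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.linalg import cholesky
from scipy.special import expit
from scipy.stats import chi2, invwishart

from ssiml.synthetic_cohort import (
    BINARY_COVARIATES,
    PROCEDURE_DUMMIES,
    PROCEDURE_TYPES,
    CohortTable,
)

__all__ = [
    "DEFAULT_COVARIATES",
    "save_draws",
    "load_draws",
    "ModelSpec",
    "PriorSpec",
    "McmcSettings",
    "PosteriorDraws",
    "FitSummary",
    "build_design",
    "ml_logistic",
    "log_likelihood",
    "fit_mcmc",
    "fit_model1_empty",
    "fit_model2_intercept",
    "fit_model3_slope",
    "coef_p",
    "test_level_variance",
    "univariate_screen",
]

#: The eleven patient covariates of the adjusted models.
DEFAULT_COVARIATES = (
    "gender_female",
    "age_ge65",
    "asa_gt2",
    "preop_ge48h",
    "altemeier_gt2",
    "endoscopic",
    "procedure_type",
    "duration_gt_p75",
    "emergency",
    "ambulatory",
    "followup_ge15",
)

_EPS = 1e-12  # probability clamp in log_likelihood


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse default priors; all hyperparameters are configurable."""

    beta_variance: float = 1e6
    variance_shape: float = 0.001  # inverse-gamma a
    variance_rate: float = 0.001  # inverse-gamma b
    wishart_df: float = 2.0  # minimal proper df for a 2x2 inverse-Wishart
    wishart_scale: tuple[float, float, float] = (1.0, 0.0, 1.0)  # (s00, s01, s11)


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length and adaptation settings.

    ``iterations`` counts total sweeps including ``burn_in``; draws are
    stored every ``thin`` sweeps after burn-in, so the number of stored
    draws is ``(iterations - burn_in) / thin``.  Acceptance targets follow
    random-walk Metropolis practice: ~44% for scalar blocks, ~35% for the
    bivariate ward blocks, ~23% for the joint fixed-effect proposal.
    """

    burn_in: int = 5000
    iterations: int = 50000
    thin: int = 10
    seed: int = 0
    target_scalar: float = 0.44
    target_bivariate: float = 0.35
    target_vector: float = 0.234

    def validate(self) -> None:
        if self.burn_in <= 0 or self.iterations <= self.burn_in:
            raise ValueError("need 0 < burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model fit.

    ``levels`` may be ``("ward",)``, ``("ward", "hospital")`` or ``()`` for
    a single-level (no random effect) Bayesian logistic regression used as
    the reference model.  ``random_slope`` names a binary covariate whose
    effect varies by ward; it must be part of ``covariates``.
    """

    covariates: tuple[str, ...] = ()
    levels: tuple[str, ...] = ("ward",)
    random_slope: Optional[str] = None
    priors: PriorSpec = PriorSpec()
    mcmc: McmcSettings = McmcSettings()

    def validate(self) -> None:
        if tuple(self.levels) not in ((), ("ward",), ("ward", "hospital")):
            raise ValueError(f"unsupported levels {self.levels!r}")
        for c in self.covariates:
            if c not in BINARY_COVARIATES and c != "procedure_type":
                raise ValueError(f"unknown covariate {c!r}")
        if self.random_slope is not None:
            if "ward" not in self.levels:
                raise ValueError("a random slope requires the ward level")
            if self.random_slope not in self.covariates:
                raise ValueError("random_slope must be one of the model covariates")
            if self.random_slope == "procedure_type":
                raise ValueError("random_slope must be a binary covariate")
        self.mcmc.validate()


@dataclass
class PosteriorDraws:
    """Stored MCMC output.

    ``ward_cov`` has one column (sigma2_00) for random-intercept fits and
    three (sigma2_00, sigma_01, sigma2_11) when a random slope is present;
    every stored draw satisfies positive semidefiniteness by construction
    (conjugate inverse-gamma / inverse-Wishart draws).  ``ward_effects``
    holds posterior means of the per-ward effects, indexed by ward id.
    """

    beta: np.ndarray
    beta_names: tuple[str, ...]
    ward_cov: Optional[np.ndarray]
    hospital_var: Optional[np.ndarray]
    ward_effects: Optional[pd.DataFrame]
    hospital_effects: Optional[pd.Series]
    random_slope: Optional[str]
    covariates: tuple[str, ...]
    acceptance: dict

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


@dataclass
class FitSummary:
    """Posterior summaries, diagnostics and any convergence warnings."""

    coefficients: pd.DataFrame
    variance_components: pd.DataFrame
    diagnostics: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design matrix and ML fit


def expand_covariates(covariates: Sequence[str]) -> tuple[str, ...]:
    """Design-column names (excluding intercept) for a covariate list."""
    out: list[str] = []
    for c in covariates:
        if c == "procedure_type":
            out.extend(PROCEDURE_DUMMIES)
        else:
            out.append(c)
    return tuple(out)


def build_design(df: pd.DataFrame, covariates: Sequence[str]):
    """Design matrix with leading intercept column for complete-case rows.

    Returns ``(X, names, mask)`` where ``mask`` flags the complete cases
    (rows with no missing outcome or covariate) the matrix was built from.
    """
    mask = df["ssi"].notna()
    for c in covariates:
        mask &= df[c].notna()
    sub = df.loc[mask]
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for c in covariates:
        if c == "procedure_type":
            for t, dummy in zip(PROCEDURE_TYPES[1:], PROCEDURE_DUMMIES):
                cols.append((sub["procedure_type"] == t).to_numpy(dtype=float))
                names.append(dummy)
        else:
            cols.append(sub[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    return X, tuple(names), mask.to_numpy()


def ml_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, ridge: float = 1e-8):
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Returns ``(beta_hat, cov)`` with ``cov`` the inverse Fisher information.
    A tiny ridge keeps the solve well-posed near separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = pi * (1 - pi) + 1e-10
        g = X.T @ (y - pi) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = X @ beta
    w = expit(eta) * (1 - expit(eta)) + 1e-10
    H = (X * w[:, None]).T @ X + ridge * np.eye(p)
    return beta, np.linalg.inv(H)


# ---------------------------------------------------------------------------
# likelihood


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-record Bernoulli log-likelihood, numerically stable in eta."""
    return y * eta - np.logaddexp(0.0, eta)


def log_likelihood(
    beta,
    ward_effects,
    hospital_effects,
    cohort: CohortTable,
    covariates: Sequence[str] = (),
    random_slope: Optional[str] = None,
) -> float:
    """Bernoulli log-likelihood of a cohort at given parameter values.

    ``beta`` is aligned with the design columns of ``covariates`` (leading
    intercept).  ``ward_effects`` maps ward id to a scalar intercept effect
    or an ``(u0, u1)`` pair when ``random_slope`` is set;
    ``hospital_effects`` maps hospital id to a scalar (or is ``None``).
    Probabilities are clamped to ``[1e-12, 1 - 1e-12]``.
    """
    df = cohort.df
    X, _, mask = build_design(df, covariates)
    sub = df.loc[mask]
    y = sub["ssi"].to_numpy(dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    if ward_effects is not None:
        f = sub[random_slope].to_numpy(dtype=float) if random_slope else None
        offsets = np.zeros(len(sub))
        for i, wid in enumerate(sub["ward_id"].to_numpy()):
            try:
                eff = ward_effects[wid]
            except KeyError:
                raise KeyError(f"no ward effect supplied for ward {wid!r}") from None
            if np.ndim(eff) == 0:
                offsets[i] = eff
            else:
                offsets[i] = eff[0] + (eff[1] * f[i] if f is not None else 0.0)
        eta = eta + offsets
    if hospital_effects is not None:
        hvals = np.empty(len(sub))
        for i, hid in enumerate(sub["hospital_id"].to_numpy()):
            try:
                hvals[i] = hospital_effects[hid]
            except KeyError:
                raise KeyError(f"no hospital effect supplied for hospital {hid!r}") from None
        eta = eta + hvals
    pi = np.clip(expit(eta), _EPS, 1.0 - _EPS)
    return float(np.sum(y * np.log(pi) + (1.0 - y) * np.log(1.0 - pi)))


# ---------------------------------------------------------------------------
# the sampler


def _summaries(draws: PosteriorDraws) -> FitSummary:
    import arviz as az

    nd = draws.n_draws
    rows = []
    diag = []
    warn: list[str] = []
    for j, name in enumerate(draws.beta_names):
        d = draws.beta[:, j]
        mean, sd = float(d.mean()), float(d.std(ddof=1))
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append(
            {
                "coefficient": name,
                "mean": mean,
                "sd": sd,
                "or": float(np.exp(mean)),
                "or_lower": float(np.exp(lo)),
                "or_upper": float(np.exp(hi)),
                "p": coef_p(d),
            }
        )
        half = (nd // 2) * 2
        split = d[:half].reshape(2, -1)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ess = float(az.ess(d[None, :]))
            rhat = float(az.rhat(split))
        diag.append({"coefficient": name, "ess": ess, "rhat": rhat})
        if rhat > 1.1:
            warn.append(f"possible non-convergence: rhat={rhat:.3f} for {name}")
        if ess < 100:
            warn.append(f"low effective sample size ({ess:.0f}) for {name}")
    vrows = []

    def _vrow(name, d):
        lo, hi = np.percentile(d, [2.5, 97.5])
        vrows.append(
            {
                "component": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "lower": float(lo),
                "upper": float(hi),
            }
        )

    if draws.ward_cov is not None:
        wc = draws.ward_cov
        _vrow("ward_var_intercept", wc[:, 0])
        if wc.shape[1] == 3:
            _vrow("ward_cov_intercept_slope", wc[:, 1])
            _vrow("ward_var_slope", wc[:, 2])
    if draws.hospital_var is not None:
        _vrow("hospital_var", draws.hospital_var)
    return FitSummary(
        coefficients=pd.DataFrame(rows),
        variance_components=pd.DataFrame(vrows),
        diagnostics=pd.DataFrame(diag),
        warnings=warn,
    )


def fit_mcmc(spec: ModelSpec, cohort: CohortTable) -> tuple[PosteriorDraws, FitSummary]:
    """Fit a multilevel logistic model by Metropolis-within-Gibbs MCMC.

    Fixed effects are initialized at the single-level ML estimates and
    proposed jointly with a Fisher-shaped random walk; cluster effects start
    at zero and are updated block-wise (vectorized over clusters); variance
    components get conjugate Gibbs updates.  Fully reproducible from
    ``spec.mcmc.seed``.
    """
    spec.validate()
    st = spec.mcmc
    rng = np.random.default_rng(st.seed)
    df = cohort.df

    X, names, mask = build_design(df, spec.covariates)
    sub = df.loc[mask]
    y = sub["ssi"].to_numpy(dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("no complete cases for the requested covariates")
    for j in range(1, p):
        if X[:, j].std() == 0:
            raise ValueError(
                f"covariate {names[j]!r} is constant in the complete cases; "
                "the model is not identifiable"
            )

    use_ward = "ward" in spec.levels
    use_hosp = "hospital" in spec.levels
    slope = spec.random_slope

    if use_ward:
        ward_codes, ward_ids = pd.factorize(sub["ward_id"], sort=True)
        J = len(ward_ids)
    else:
        ward_codes, ward_ids, J = None, None, 0
    if use_hosp:
        hosp_codes, hosp_ids = pd.factorize(sub["hospital_id"], sort=True)
        K = len(hosp_ids)
    else:
        hosp_codes, hosp_ids, K = None, None, 0
    f = sub[slope].to_numpy(dtype=float) if slope else None

    pri = spec.priors
    beta, fisher_cov = ml_logistic(X, y)
    L_prop = cholesky(fisher_cov + 1e-10 * np.eye(p))
    log_s_beta = np.log(2.38 / np.sqrt(p))

    u0 = np.zeros(J) if use_ward else None
    u1 = np.zeros(J) if slope else None
    v = np.zeros(K) if use_hosp else None
    s2w = 0.5 if (use_ward and not slope) else None
    Sigma = np.array([[0.5, 0.0], [0.0, 0.25]]) if slope else None
    s2h = 0.25 if use_hosp else None
    S0 = np.array(
        [
            [pri.wishart_scale[0], pri.wishart_scale[1]],
            [pri.wishart_scale[1], pri.wishart_scale[2]],
        ]
    )

    log_sw = np.full(J, np.log(1.0)) if use_ward else None
    log_sh = np.full(K, np.log(1.0)) if use_hosp else None
    # scales of the recentering / rescaling moves (adapted in burn-in)
    dim_w = 2 if slope else 1
    log_rc = np.full(dim_w, 0.5 * np.log(1.0 / max(J, 1))) if use_ward else None
    log_sc = np.log(0.1) if use_ward else None
    log_rch = 0.5 * np.log(1.0 / max(K, 1)) if use_hosp else None
    log_sch = np.log(0.1) if use_hosp else None
    idx_slope = names.index(slope) if slope else None

    offset_w = np.zeros(n)
    offset_h = np.zeros(n)
    Xb = X @ beta
    ll_rec = _bernoulli_ll(y, Xb + offset_w + offset_h)

    n_store = (st.iterations - st.burn_in) // st.thin
    beta_out = np.empty((n_store, p))
    wc_out = np.empty((n_store, 3 if slope else 1)) if use_ward else None
    hv_out = np.empty(n_store) if use_hosp else None
    u0_sum = np.zeros(J) if use_ward else None
    u1_sum = np.zeros(J) if slope else None
    v_sum = np.zeros(K) if use_hosp else None

    acc_beta = 0
    acc_ward = 0.0
    acc_hosp = 0.0
    n_kept = 0
    gamma = 0.05  # Robbins-Monro step during burn-in

    for it in range(st.iterations):
        adapting = it < st.burn_in

        # ---- fixed effects: joint random-walk Metropolis
        prop = beta + np.exp(log_s_beta) * (L_prop @ rng.standard_normal(p))
        Xb_prop = X @ prop
        ll_prop = _bernoulli_ll(y, Xb_prop + offset_w + offset_h)
        d = (
            ll_prop.sum()
            - ll_rec.sum()
            + 0.5 * (beta @ beta - prop @ prop) / pri.beta_variance
        )
        a = min(1.0, np.exp(min(d, 0.0)))
        if rng.random() < a:
            beta, Xb, ll_rec = prop, Xb_prop, ll_prop
            if not adapting:
                acc_beta += 1
        if adapting:
            log_s_beta += gamma * (a - st.target_vector)

        # ---- ward effect blocks (vectorized accept/reject per ward)
        if use_ward:
            if slope:
                Ls = cholesky(Sigma + 1e-10 * np.eye(2))
                step = np.exp(log_sw)[:, None] * (rng.standard_normal((J, 2)) @ Ls.T)
                u0p, u1p = u0 + step[:, 0], u1 + step[:, 1]
                P = np.linalg.inv(Sigma + 1e-12 * np.eye(2))
                q_cur = -0.5 * (
                    P[0, 0] * u0**2 + 2 * P[0, 1] * u0 * u1 + P[1, 1] * u1**2
                )
                q_prop = -0.5 * (
                    P[0, 0] * u0p**2 + 2 * P[0, 1] * u0p * u1p + P[1, 1] * u1p**2
                )
                d_eta = (u0p - u0)[ward_codes] + (u1p - u1)[ward_codes] * f
            else:
                step = np.exp(log_sw) * rng.standard_normal(J)
                u0p = u0 + step
                q_cur = -0.5 * u0**2 / s2w
                q_prop = -0.5 * u0p**2 / s2w
                d_eta = (u0p - u0)[ward_codes]
            ll_prop = _bernoulli_ll(y, Xb + offset_w + offset_h + d_eta)
            d_ward = (
                np.bincount(ward_codes, weights=ll_prop - ll_rec, minlength=J)
                + q_prop
                - q_cur
            )
            a_ward = np.exp(np.minimum(d_ward, 0.0))
            acc = rng.random(J) < a_ward
            if slope:
                u0 = np.where(acc, u0p, u0)
                u1 = np.where(acc, u1p, u1)
            else:
                u0 = np.where(acc, u0p, u0)
            acc_rec = acc[ward_codes]
            offset_w = np.where(acc_rec, offset_w + d_eta, offset_w)
            ll_rec = np.where(acc_rec, ll_prop, ll_rec)
            if adapting:
                target = st.target_bivariate if slope else st.target_scalar
                log_sw += gamma * (a_ward - target)
            else:
                acc_ward += acc.mean()

        # ---- hospital effect blocks
        if use_hosp:
            step = np.exp(log_sh) * rng.standard_normal(K)
            vp = v + step
            d_eta = (vp - v)[hosp_codes]
            ll_prop = _bernoulli_ll(y, Xb + offset_w + offset_h + d_eta)
            d_hosp = (
                np.bincount(hosp_codes, weights=ll_prop - ll_rec, minlength=K)
                - 0.5 * (vp**2 - v**2) / s2h
            )
            a_hosp = np.exp(np.minimum(d_hosp, 0.0))
            acc = rng.random(K) < a_hosp
            v = np.where(acc, vp, v)
            acc_rec = acc[hosp_codes]
            offset_h = np.where(acc_rec, offset_h + d_eta, offset_h)
            ll_rec = np.where(acc_rec, ll_prop, ll_rec)
            if adapting:
                log_sh += gamma * (a_hosp - st.target_scalar)
            else:
                acc_hosp += acc.mean()

        # ---- variance components: conjugate Gibbs
        if use_ward:
            if slope:
                U = np.column_stack([u0, u1])
                S_post = S0 + U.T @ U
                Sigma = invwishart.rvs(
                    df=pri.wishart_df + J, scale=S_post, random_state=rng
                )
            else:
                shape = pri.variance_shape + 0.5 * J
                rate = pri.variance_rate + 0.5 * float(u0 @ u0)
                s2w = 1.0 / rng.gamma(shape, 1.0 / rate)
        if use_hosp:
            shape = pri.variance_shape + 0.5 * K
            rate = pri.variance_rate + 0.5 * float(v @ v)
            s2h = 1.0 / rng.gamma(shape, 1.0 / rate)

        # ---- recentering move: shift every ward effect by a common delta,
        # absorbed into the corresponding fixed effect(s).  Leaves the
        # linear predictor (hence the likelihood) invariant and breaks the
        # strong posterior coupling between the intercept and mean effect.
        if use_ward:
            delta = np.exp(log_rc) * rng.standard_normal(dim_w)
            if slope:
                P = np.linalg.inv(Sigma + 1e-12 * np.eye(2))
                s_u = np.array([u0.sum(), u1.sum()])
                d_pri = -float(delta @ P @ s_u) - 0.5 * J * float(delta @ P @ delta)
                b_new0 = beta[0] - delta[0]
                b_new1 = beta[idx_slope] - delta[1]
                d_pri += (
                    0.5
                    * (
                        beta[0] ** 2
                        - b_new0**2
                        + beta[idx_slope] ** 2
                        - b_new1**2
                    )
                    / pri.beta_variance
                )
            else:
                d_pri = (
                    -delta[0] * u0.sum() / s2w - 0.5 * J * delta[0] ** 2 / s2w
                )
                b_new0 = beta[0] - delta[0]
                d_pri += 0.5 * (beta[0] ** 2 - b_new0**2) / pri.beta_variance
            a_rc = min(1.0, np.exp(min(d_pri, 0.0)))
            if rng.random() < a_rc:
                u0 = u0 + delta[0]
                shift = np.full(n, delta[0])
                beta = beta.copy()
                beta[0] -= delta[0]
                if slope:
                    u1 = u1 + delta[1]
                    beta[idx_slope] -= delta[1]
                    shift = shift + delta[1] * f
                offset_w = offset_w + shift
                Xb = Xb - shift  # x_slope equals f on complete cases
            if adapting:
                log_rc += gamma * (a_rc - st.target_scalar)

        # ---- rescaling move: jointly scale all ward effects and their
        # (co)variance, which decouples the variance from the slow random
        # walk of the effects (the centered-parameterization funnel).
        if use_ward:
            eps = np.exp(log_sc) * rng.standard_normal()
            c = np.exp(eps)
            offw_prop = c * offset_w
            ll_prop = _bernoulli_ll(y, Xb + offw_prop + offset_h)
            d_scale = float(ll_prop.sum() - ll_rec.sum())
            if slope:
                tr = float(np.trace(S0 @ np.linalg.inv(Sigma + 1e-12 * np.eye(2))))
                d_scale += (
                    dim_w * (dim_w + 1) * eps
                    - dim_w * (pri.wishart_df + dim_w + 1) * eps
                    - 0.5 * (c**-2 - 1.0) * tr
                )
            else:
                d_scale += (
                    2.0 * eps
                    - 2.0 * (pri.variance_shape + 1.0) * eps
                    - pri.variance_rate * (c**-2 - 1.0) / s2w
                )
            a_sc = min(1.0, np.exp(min(d_scale, 0.0)))
            if rng.random() < a_sc:
                u0 = c * u0
                if slope:
                    u1 = c * u1
                    Sigma = c * c * Sigma
                else:
                    s2w = c * c * s2w
                offset_w = offw_prop
                ll_rec = ll_prop
            if adapting:
                log_sc += gamma * (a_sc - st.target_scalar)

        # ---- same two moves for the hospital level
        if use_hosp:
            delta_h = np.exp(log_rch) * rng.standard_normal()
            d_pri = -delta_h * v.sum() / s2h - 0.5 * K * delta_h**2 / s2h
            b_new0 = beta[0] - delta_h
            d_pri += 0.5 * (beta[0] ** 2 - b_new0**2) / pri.beta_variance
            a_rch = min(1.0, np.exp(min(d_pri, 0.0)))
            if rng.random() < a_rch:
                v = v + delta_h
                beta = beta.copy()
                beta[0] -= delta_h
                offset_h = offset_h + delta_h
                Xb = Xb - delta_h
            if adapting:
                log_rch += gamma * (a_rch - st.target_scalar)

            eps = np.exp(log_sch) * rng.standard_normal()
            c = np.exp(eps)
            offh_prop = c * offset_h
            ll_prop = _bernoulli_ll(y, Xb + offset_w + offh_prop)
            d_scale = (
                float(ll_prop.sum() - ll_rec.sum())
                + 2.0 * eps
                - 2.0 * (pri.variance_shape + 1.0) * eps
                - pri.variance_rate * (c**-2 - 1.0) / s2h
            )
            a_sch = min(1.0, np.exp(min(d_scale, 0.0)))
            if rng.random() < a_sch:
                v = c * v
                s2h = c * c * s2h
                offset_h = offh_prop
                ll_rec = ll_prop
            if adapting:
                log_sch += gamma * (a_sch - st.target_scalar)

        # ---- storage
        if it >= st.burn_in and (it - st.burn_in) % st.thin == 0:
            beta_out[n_kept] = beta
            if use_ward:
                if slope:
                    wc_out[n_kept] = (Sigma[0, 0], Sigma[0, 1], Sigma[1, 1])
                else:
                    wc_out[n_kept] = s2w
                u0_sum += u0
                if slope:
                    u1_sum += u1
            if use_hosp:
                hv_out[n_kept] = s2h
                v_sum += v
            n_kept += 1

    post_iters = st.iterations - st.burn_in
    acceptance = {"beta": acc_beta / post_iters}
    if use_ward:
        acceptance["ward"] = acc_ward / post_iters
    if use_hosp:
        acceptance["hospital"] = acc_hosp / post_iters

    ward_eff = None
    if use_ward:
        cols = {"u0": u0_sum / n_kept}
        if slope:
            cols["u1"] = u1_sum / n_kept
        ward_eff = pd.DataFrame(cols, index=pd.Index(ward_ids, name="ward_id"))
    hosp_eff = None
    if use_hosp:
        hosp_eff = pd.Series(
            v_sum / n_kept, index=pd.Index(hosp_ids, name="hospital_id"), name="v"
        )

    draws = PosteriorDraws(
        beta=beta_out[:n_kept],
        beta_names=names,
        ward_cov=wc_out[:n_kept] if use_ward else None,
        hospital_var=hv_out[:n_kept] if use_hosp else None,
        ward_effects=ward_eff,
        hospital_effects=hosp_eff,
        random_slope=slope,
        covariates=tuple(spec.covariates),
        acceptance=acceptance,
    )
    return draws, _summaries(draws)


# ---------------------------------------------------------------------------
# the three canonical model fits


def fit_model1_empty(
    cohort: CohortTable,
    levels: tuple[str, ...] = ("ward", "hospital"),
    mcmc: Optional[McmcSettings] = None,
):
    """Empty (variance-partition) model: random intercepts, no covariates."""
    spec = ModelSpec(covariates=(), levels=levels, mcmc=mcmc or McmcSettings())
    return fit_mcmc(spec, cohort)


def fit_model2_intercept(
    cohort: CohortTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    mcmc: Optional[McmcSettings] = None,
):
    """Random-intercept model: patient covariates, ward random intercept."""
    spec = ModelSpec(
        covariates=tuple(covariates), levels=("ward",), mcmc=mcmc or McmcSettings()
    )
    return fit_mcmc(spec, cohort)


def fit_model3_slope(
    cohort: CohortTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    slope_covariate: str = "followup_ge15",
    mcmc: Optional[McmcSettings] = None,
):
    """Random-coefficient model: one covariate effect varies between wards."""
    spec = ModelSpec(
        covariates=tuple(covariates),
        levels=("ward",),
        random_slope=slope_covariate,
        mcmc=mcmc or McmcSettings(),
    )
    return fit_mcmc(spec, cohort)


# ---------------------------------------------------------------------------
# posterior archive I/O


def save_draws(draws: PosteriorDraws, path) -> None:
    """Archive posterior draws as a compressed ``.npz`` file."""
    payload: dict = {
        "beta": draws.beta,
        "beta_names": np.array(draws.beta_names),
        "covariates": np.array(draws.covariates),
        "random_slope": np.array(draws.random_slope or ""),
    }
    if draws.ward_cov is not None:
        payload["ward_cov"] = draws.ward_cov
        payload["ward_ids"] = draws.ward_effects.index.to_numpy().astype(str)
        payload["ward_u0"] = draws.ward_effects["u0"].to_numpy()
        if draws.random_slope:
            payload["ward_u1"] = draws.ward_effects["u1"].to_numpy()
    if draws.hospital_var is not None:
        payload["hospital_var"] = draws.hospital_var
        payload["hospital_ids"] = draws.hospital_effects.index.to_numpy().astype(str)
        payload["hospital_v"] = draws.hospital_effects.to_numpy()
    np.savez_compressed(path, **payload)


def load_draws(path) -> PosteriorDraws:
    """Load a posterior archive written by :func:`save_draws`."""
    with np.load(path, allow_pickle=False) as z:
        slope = str(z["random_slope"]) or None
        ward_eff = None
        ward_cov = None
        if "ward_cov" in z:
            ward_cov = z["ward_cov"]
            cols = {"u0": z["ward_u0"]}
            if slope:
                cols["u1"] = z["ward_u1"]
            ward_eff = pd.DataFrame(
                cols, index=pd.Index(z["ward_ids"], name="ward_id")
            )
        hosp_var = z["hospital_var"] if "hospital_var" in z else None
        hosp_eff = (
            pd.Series(
                z["hospital_v"],
                index=pd.Index(z["hospital_ids"], name="hospital_id"),
                name="v",
            )
            if "hospital_var" in z
            else None
        )
        return PosteriorDraws(
            beta=z["beta"],
            beta_names=tuple(str(s) for s in z["beta_names"]),
            ward_cov=ward_cov,
            hospital_var=hosp_var,
            ward_effects=ward_eff,
            hospital_effects=hosp_eff,
            random_slope=slope,
            covariates=tuple(str(s) for s in z["covariates"]),
            acceptance={},
        )


# ---------------------------------------------------------------------------
# posterior tail p-values


def coef_p(draws) -> float:
    """Two-sided posterior tail probability for one coefficient.

    ``2 * min(P(theta > 0), P(theta < 0))``, floored at ``2 / n_draws``
    because a tail never visited by the chain is not evidence of a zero
    tail probability.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 100:
        raise ValueError(f"need at least 100 draws, got {d.size}")
    p_pos = float((d > 0).mean())
    p_neg = float((d < 0).mean())
    return max(2.0 * min(p_pos, p_neg), 2.0 / d.size)


# ---------------------------------------------------------------------------
# level-variance test (Laplace-approximate likelihood-ratio on the boundary)


def _laplace_empty(y, ward, hosp, max_newton: int = 200):
    """Laplace-approximate marginal log-likelihood maximized over an empty
    multilevel logistic model with the given random levels.

    ``ward`` / ``hosp`` are integer cluster codes or ``None``.  Returns the
    maximized approximate log-likelihood.  The inner mode-finding alternates
    damped Newton steps on the two diagonal effect blocks; the log-
    determinant of the joint Hessian uses the Schur complement, which stays
    diagonal because each ward belongs to exactly one hospital.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    n = y.size
    J = int(ward.max()) + 1 if ward is not None else 0
    K = int(hosp.max()) + 1 if hosp is not None else 0
    ward_hosp = None
    if ward is not None and hosp is not None:
        ward_hosp = np.zeros(J, dtype=int)
        ward_hosp[ward] = hosp

    def neg_marginal(params):
        b0 = params[0]
        idx = 1
        if ward is not None:
            s2w = np.exp(params[idx])
            idx += 1
        if hosp is not None:
            s2h = np.exp(params[idx])
        u = np.zeros(J) if ward is not None else None
        v = np.zeros(K) if hosp is not None else None
        for _ in range(max_newton):
            eta = np.full(n, b0)
            if ward is not None:
                eta += u[ward]
            if hosp is not None:
                eta += v[hosp]
            pi = expit(eta)
            w = pi * (1 - pi)
            moved = 0.0
            if ward is not None:
                g = np.bincount(ward, weights=y - pi, minlength=J) - u / s2w
                h = np.bincount(ward, weights=w, minlength=J) + 1.0 / s2w
                du = g / h
                u = u + du
                moved = max(moved, np.max(np.abs(du)))
            if hosp is not None:
                eta = np.full(n, b0) + (u[ward] if ward is not None else 0.0) + v[hosp]
                pi = expit(eta)
                w = pi * (1 - pi)
                g = np.bincount(hosp, weights=y - pi, minlength=K) - v / s2h
                h = np.bincount(hosp, weights=w, minlength=K) + 1.0 / s2h
                dv = g / h
                v = v + dv
                moved = max(moved, np.max(np.abs(dv)))
            if moved < 1e-10:
                break
        eta = np.full(n, b0)
        if ward is not None:
            eta += u[ward]
        if hosp is not None:
            eta += v[hosp]
        pi = expit(eta)
        w = pi * (1 - pi)
        ll = float(np.sum(_bernoulli_ll(y, eta)))
        out = ll
        if ward is not None:
            s_j = np.bincount(ward, weights=w, minlength=J)
            h_u = s_j + 1.0 / s2w
            out += -0.5 * float(u @ u) / s2w - 0.5 * J * np.log(s2w)
            out -= 0.5 * float(np.sum(np.log(h_u)))
            if hosp is not None:
                t_k = np.bincount(hosp, weights=w, minlength=K)
                # Schur complement of the ward block: diagonal over hospitals
                corr = np.bincount(ward_hosp, weights=s_j**2 / h_u, minlength=K)
                h_v = t_k + 1.0 / s2h - corr
                out += -0.5 * float(v @ v) / s2h - 0.5 * K * np.log(s2h)
                out -= 0.5 * float(np.sum(np.log(np.maximum(h_v, 1e-300))))
        elif hosp is not None:
            t_k = np.bincount(hosp, weights=w, minlength=K)
            h_v = t_k + 1.0 / s2h
            out += -0.5 * float(v @ v) / s2h - 0.5 * K * np.log(s2h)
            out -= 0.5 * float(np.sum(np.log(h_v)))
        return -out

    b0_start = float(np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6)))
    x0 = [b0_start]
    if ward is not None:
        x0.append(np.log(0.5))
    if hosp is not None:
        x0.append(np.log(0.1))
    res = minimize(neg_marginal, np.asarray(x0), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    return -float(res.fun)


def test_level_variance(
    cohort: CohortTable,
    levels_full: Sequence[str],
    levels_reduced: Sequence[str],
) -> float:
    """Likelihood-ratio test for an additional random level in the empty model.

    Both empty models are fitted by a Laplace approximation to the marginal
    likelihood; twice the log-likelihood difference is referred to the
    50:50 mixture of a point mass at zero and chi-square(1) appropriate for
    a variance tested on the boundary of its parameter space.  Returns the
    p-value.
    """
    full = tuple(levels_full)
    red = tuple(levels_reduced)
    if not set(red) <= set(full):
        raise ValueError("reduced levels must be a subset of the full levels")
    for lv in full:
        if lv not in ("ward", "hospital"):
            raise ValueError(f"unknown level {lv!r}")
    df = cohort.df.loc[cohort.df["ssi"].notna()]
    y = df["ssi"].to_numpy(dtype=float)

    def codes(levels):
        w = pd.factorize(df["ward_id"], sort=True)[0] if "ward" in levels else None
        h = pd.factorize(df["hospital_id"], sort=True)[0] if "hospital" in levels else None
        return w, h

    if set(full) == set(red):
        return 1.0
    ll_full = _laplace_empty(y, *codes(full))
    ll_red = _laplace_empty(y, *codes(red))
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    if stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, df=1))


# despite its name this is a statistical test, not a pytest case
test_level_variance.__test__ = False


# ---------------------------------------------------------------------------
# univariate screening


def univariate_screen(
    cohort: CohortTable,
    candidates: Sequence[str],
    alpha: float = 0.20,
    mcmc: Optional[McmcSettings] = None,
) -> list[str]:
    """Liberal univariate pre-selection of candidate covariates.

    Each candidate is fitted alone in a ward-random-intercept model; it is
    retained when its two-sided posterior tail probability falls below
    ``alpha`` (any non-reference level suffices for the multi-category
    procedure type).  The permissive default threshold (0.20) deliberately
    over-selects, as is usual before a multivariable model.
    """
    st = mcmc or McmcSettings(burn_in=1000, iterations=6000, thin=5)
    retained = []
    for i, cand in enumerate(candidates):
        spec = ModelSpec(
            covariates=(cand,),
            levels=("ward",),
            mcmc=replace(st, seed=st.seed + 1000 + i),
        )
        draws, _ = fit_mcmc(spec, cohort)
        ps = [
            coef_p(draws.beta[:, j])
            for j, name in enumerate(draws.beta_names)
            if name != "intercept"
        ]
        if min(ps) < alpha:
            retained.append(cand)
    return retained
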