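"""Out-of-sample validation: predicted probabilities, SIR and ROC comparison.

A fitted multilevel model is applied to an independent cohort by combining
the fixed-effect coefficients with a **ward-effect policy**:

* ``zero`` — ward effects set to 0 (pure case-mix prediction, equivalent to
  the single-level use of the coefficients);
* ``training`` — posterior-mean effects for wards present in the training
  fit, 0 for unseen wards;
* ``empirical_bayes`` — ward effects re-estimated on the evaluation cohort
  itself as penalized (shrunken) per-ward modes given the fixed
  coefficients and ward covariance from training.  This is the default: a
  surveillance system scoring a ward always has that ward's own recent
  outcome data, and without ward information a hierarchical model cannot
  discriminate better than its single-level counterpart.

Discrimination is summarized by the midrank (Mann-Whitney) AUC.  Standard
errors use the Hanley-McNeil binormal-free formula; paired model
comparisons default to the placement-value (DeLong) covariance
construction, with a Hanley-McNeil-style engine that accepts an externally
chosen AUC correlation for fidelity with older workflows.

The standardized infection ratio (SIR) is the observed infection count of
a unit divided by the model-expected count (sum of predicted
probabilities); values above 1 flag units with more infections than their
case-mix predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from ssiml.hierarchical_model import PosteriorDraws, build_design
from ssiml.synthetic_cohort import CohortTable

__all__ = [
    "RocComparison",
    "SirResult",
    "predict_prob",
    "estimate_ward_effects",
    "sir",
    "sir_by_ward",
    "auc",
    "roc_curve",
    "hanley_mcneil_se",
    "compare_aucs",
]


@dataclass(frozen=True)
class RocComparison:
    """Two correlated AUCs and their paired comparison."""

    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    r: float
    z: float
    p: float
    engine: str


@dataclass(frozen=True)
class SirResult:
    """Observed vs expected infection counts for a ward or the whole cohort."""

    scope: str
    observed: int
    expected: float
    sir: float


# ---------------------------------------------------------------------------
# prediction


def _posterior_mean_ward_cov(draws: PosteriorDraws) -> np.ndarray:
    wc = draws.ward_cov.mean(axis=0)
    if wc.shape == (1,):
        return np.array([[wc[0]]])
    return np.array([[wc[0], wc[1]], [wc[1], wc[2]]])


def predict_prob(
    draws: PosteriorDraws,
    cohort: CohortTable,
    ward_effect_policy: str = "empirical_bayes",
) -> np.ndarray:
    """Per-record SSI probabilities from a fit, under a ward-effect policy.

    Uses posterior-mean coefficients; returns an array aligned with the
    complete-case records of the cohort (records with a missing outcome or
    covariate get NaN).
    """
    if ward_effect_policy not in ("zero", "training", "empirical_bayes"):
        raise ValueError(f"unknown ward_effect_policy {ward_effect_policy!r}")
    df = cohort.df
    X, names, mask = build_design(df, draws.covariates)
    if names != draws.beta_names:
        raise ValueError(
            f"cohort design columns {names} do not match fitted coefficients "
            f"{draws.beta_names}"
        )
    beta_hat = draws.beta.mean(axis=0)
    eta = X @ beta_hat
    sub = df.loc[mask]

    if draws.ward_cov is not None and ward_effect_policy != "zero":
        f = (
            sub[draws.random_slope].to_numpy(dtype=float)
            if draws.random_slope
            else None
        )
        if ward_effect_policy == "training":
            eff = draws.ward_effects
            u0 = sub["ward_id"].map(eff["u0"]).fillna(0.0).to_numpy(dtype=float)
            eta = eta + u0
            if draws.random_slope:
                u1 = sub["ward_id"].map(eff["u1"]).fillna(0.0).to_numpy(dtype=float)
                eta = eta + u1 * f
        else:  # empirical_bayes on the evaluation cohort
            cov = _posterior_mean_ward_cov(draws)
            eff = estimate_ward_effects(
                beta_hat,
                cov,
                cohort,
                covariates=draws.covariates,
                slope_covariate=draws.random_slope,
            )
            codes = sub["ward_id"].to_numpy()
            u0 = eff["u0"].reindex(codes).to_numpy(dtype=float)
            eta = eta + u0
            if draws.random_slope:
                u1 = eff["u1"].reindex(codes).to_numpy(dtype=float)
                eta = eta + u1 * f

    out = np.full(len(df), np.nan)
    out[mask] = expit(eta)
    return out


def estimate_ward_effects(
    beta_fixed: np.ndarray,
    ward_cov_fixed: np.ndarray,
    cohort: CohortTable,
    covariates: Sequence[str] = (),
    slope_covariate: Optional[str] = None,
) -> pd.DataFrame:
    """Empirical-Bayes (posterior-mode) ward effects at fixed hyperparameters.

    Maximizes, per ward, the Bernoulli log-likelihood at fixed coefficients
    plus the quadratic penalty from the inverse ward covariance — a ridge
    (1e-8) pseudo-inverse handles singular covariances.  Effects shrink to
    zero for wards with little data or a small covariance; a ward absent
    from the cohort would sit exactly at the prior mode, zero.

    Returns a DataFrame indexed by ward id with column ``u0`` (and ``u1``
    when ``slope_covariate`` is set).  The block-diagonal Newton iteration
    is run jointly (vectorized over wards).
    """
    df = cohort.df
    X, _, mask = build_design(df, covariates)
    sub = df.loc[mask]
    y = sub["ssi"].to_numpy(dtype=float)
    w, ward_ids = pd.factorize(sub["ward_id"], sort=True)
    J = len(ward_ids)
    base = X @ np.asarray(beta_fixed, dtype=float)

    cov = np.atleast_2d(np.asarray(ward_cov_fixed, dtype=float))
    dim = 2 if slope_covariate else 1
    if cov.shape != (dim, dim):
        raise ValueError(f"ward covariance must be {dim}x{dim}, got {cov.shape}")
    prec = np.linalg.pinv(cov + 1e-8 * np.eye(dim))
    if slope_covariate:
        f = sub[slope_covariate].to_numpy(dtype=float)

    def per_ward_objective(u: np.ndarray) -> np.ndarray:
        eta = base + u[w, 0] + (u[w, 1] * f if dim == 2 else 0.0)
        ll = y * eta - np.logaddexp(0.0, eta)
        pen = 0.5 * np.einsum("ji,ik,jk->j", u, prec, u)
        return np.bincount(w, weights=ll, minlength=J) - pen

    u = np.zeros((J, dim))
    obj = per_ward_objective(u)
    for _ in range(200):
        eta = base + u[w, 0] + (u[w, 1] * f if dim == 2 else 0.0)
        pi = expit(eta)
        wt = pi * (1 - pi)
        g0 = np.bincount(w, weights=y - pi, minlength=J)
        h00 = np.bincount(w, weights=wt, minlength=J)
        du = np.empty_like(u)
        if dim == 1:
            du[:, 0] = (g0 - prec[0, 0] * u[:, 0]) / (h00 + prec[0, 0])
        else:
            g1 = np.bincount(w, weights=(y - pi) * f, minlength=J)
            h01 = np.bincount(w, weights=wt * f, minlength=J)
            h11 = np.bincount(w, weights=wt * f * f, minlength=J)
            grad0 = g0 - (prec[0, 0] * u[:, 0] + prec[0, 1] * u[:, 1])
            grad1 = g1 - (prec[1, 0] * u[:, 0] + prec[1, 1] * u[:, 1])
            a = h00 + prec[0, 0]
            b = h01 + prec[0, 1]
            c = h11 + prec[1, 1]
            det = a * c - b * b
            du[:, 0] = (c * grad0 - b * grad1) / det
            du[:, 1] = (a * grad1 - b * grad0) / det
        # backtracking line search per ward: the penalized log-likelihood is
        # strictly concave, so a damped Newton step always ascends
        alpha = np.ones(J)
        for _bt in range(40):
            u_try = u + alpha[:, None] * du
            obj_try = per_ward_objective(u_try)
            worse = obj_try < obj - 1e-13
            if not worse.any():
                break
            alpha[worse] *= 0.5
        improved = obj_try >= obj
        step = np.where(improved[:, None], alpha[:, None] * du, 0.0)
        u = u + step
        obj = np.where(improved, obj_try, obj)
        if np.max(np.abs(step)) < 1e-10:
            break

    cols = {"u0": u[:, 0]}
    if dim == 2:
        cols["u1"] = u[:, 1]
    return pd.DataFrame(cols, index=pd.Index(ward_ids, name="ward_id"))


# ---------------------------------------------------------------------------
# SIR


def sir(observed: int, expected: float) -> float:
    """Standardized infection ratio: observed over model-expected count."""
    if observed < 0 or int(observed) != observed:
        raise ValueError("observed count must be a non-negative integer")
    if not expected > 0:
        raise ValueError(f"expected count must be > 0, got {expected!r}")
    return float(observed) / float(expected)


def sir_by_ward(cohort: CohortTable, probs: np.ndarray) -> list[SirResult]:
    """Per-ward and overall SIRs from per-record predicted probabilities.

    Records with NaN probability (incomplete cases) are excluded from both
    the observed and expected counts.  Wards with zero expected count are
    skipped.
    """
    df = cohort.df
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(df),):
        raise ValueError("probs must align with the cohort records")
    ok = ~np.isnan(probs) & df["ssi"].notna().to_numpy()
    sub = df.loc[ok]
    p = probs[ok]
    results: list[SirResult] = []
    grouped = pd.DataFrame(
        {"ward_id": sub["ward_id"].to_numpy(), "ssi": sub["ssi"].to_numpy(dtype=float), "p": p}
    ).groupby("ward_id", observed=True)
    for wid, g in grouped:
        exp_count = float(g["p"].sum())
        if exp_count > 0:
            obs = int(g["ssi"].sum())
            results.append(SirResult(str(wid), obs, exp_count, obs / exp_count))
    total_exp = float(p.sum())
    total_obs = int(sub["ssi"].sum())
    results.append(SirResult("overall", total_obs, total_exp, total_obs / total_exp))
    return results


# ---------------------------------------------------------------------------
# ROC / AUC


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both outcome classes present")
    if not np.all(pos | neg):
        raise ValueError("labels must be 0 or 1")
    return pos, neg


def auc(scores, labels) -> float:
    """Midrank (Mann-Whitney) estimate of the area under the ROC curve.

    Ties between a positive and a negative score contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    ranks = rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC coordinates at every distinct threshold.

    Returns a DataFrame with columns ``threshold``, ``fpr``, ``tpr`` in
    decreasing-threshold order, starting at (0, 0) and ending at (1, 1);
    its trapezoidal area equals the midrank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    is_pos = pos[order].astype(float)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(is_pos)[distinct]
    fp = np.cumsum(1.0 - is_pos)[distinct]
    n1, n0 = pos.sum(), neg.sum()
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fp / n0],
            "tpr": np.r_[0.0, tp / n1],
        }
    )


def hanley_mcneil_se(A: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil (1982) standard error of a single AUC.

    Uses the exponential-model moments Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    q1 = A / (2.0 - A)
    q2 = 2.0 * A * A / (1.0 + A)
    var = (
        A * (1.0 - A)
        + (n_pos - 1) * (q1 - A * A)
        + (n_neg - 1) * (q2 - A * A)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    s_pos, s_neg = scores[pos], scores[neg]
    n1, n0 = len(s_pos), len(s_neg)
    all_ranks = rankdata(np.r_[s_pos, s_neg])
    v10 = (all_ranks[:n1] - rankdata(s_pos)) / n0
    v01 = 1.0 - (all_ranks[n1:] - rankdata(s_neg)) / n1
    return v10, v01


def compare_aucs(
    scores_a,
    scores_b,
    labels,
    engine: str = "delong",
    r: Optional[float] = None,
) -> RocComparison:
    """Paired comparison of two models' AUCs on the same records.

    ``engine="delong"`` (default) estimates the covariance of the two AUC
    estimates from paired placement values and is fully data-driven.
    ``engine="hanley-mcneil"`` combines the Hanley-McNeil SEs with an AUC
    correlation ``r``; when ``r`` is not supplied it is approximated by the
    average of the within-class Pearson correlations of the paired scores
    (the quantity the published lookup table is indexed by — a slightly
    conservative stand-in for the tabulated value).

    Reported ``se_a``/``se_b`` are always the Hanley-McNeil single-AUC
    standard errors; ``z`` and ``p`` come from the selected engine.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned 1-D arrays")
    pos, neg = _check_labels(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())

    auc_a = auc(scores_a, labels)
    auc_b = auc(scores_b, labels)
    se_a = hanley_mcneil_se(auc_a, n1, n0)
    se_b = hanley_mcneil_se(auc_b, n1, n0)

    if engine == "delong":
        v10a, v01a = _placements(scores_a, pos, neg)
        v10b, v01b = _placements(scores_b, pos, neg)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        cov_mat = s10 / n1 + s01 / n0
        var_diff = cov_mat[0, 0] + cov_mat[1, 1] - 2.0 * cov_mat[0, 1]
        denom = np.sqrt(cov_mat[0, 0] * cov_mat[1, 1])
        r_used = float(cov_mat[0, 1] / denom) if denom > 0 else 0.0
        se_diff = float(np.sqrt(max(var_diff, 0.0)))
    elif engine == "hanley-mcneil":
        if r is None:
            r_pos = _safe_corr(scores_a[pos], scores_b[pos])
            r_neg = _safe_corr(scores_a[neg], scores_b[neg])
            r = 0.5 * (r_pos + r_neg)
        r_used = float(np.clip(r, -1.0, 1.0))
        se_diff = float(
            np.sqrt(max(se_a**2 + se_b**2 - 2.0 * r_used * se_a * se_b, 0.0))
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if se_diff == 0.0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / se_diff
        p = float(2.0 * norm.sf(abs(z)))
    return RocComparison(auc_a, auc_b, se_a, se_b, r_used, float(z), p, engine)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
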