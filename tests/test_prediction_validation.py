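"""Prediction policies, SIR, AUC and paired ROC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from conftest import make_cohort
from ssiml.hierarchical_model import PosteriorDraws, build_design, ml_logistic
from ssiml.prediction_validation import (
    auc,
    compare_aucs,
    estimate_ward_effects,
    hanley_mcneil_se,
    predict_prob,
    roc_curve,
    sir,
    sir_by_ward,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair-count oracle: wins + half-ties over all pos/neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def fake_draws(beta, names, covariates, ward_ids=None, ward_cov=None,
               ward_u0=None, ward_u1=None, slope=None):
    """PosteriorDraws with a degenerate posterior at the given values."""
    beta = np.tile(np.asarray(beta, float), (120, 1))
    ward_effects = None
    wc = None
    if ward_ids is not None:
        cols = {"u0": np.asarray(ward_u0, float)}
        if slope:
            cols["u1"] = np.asarray(ward_u1, float)
        ward_effects = pd.DataFrame(cols, index=pd.Index(ward_ids, name="ward_id"))
        wc = np.tile(np.asarray(ward_cov, float), (120, 1))
    return PosteriorDraws(
        beta=beta, beta_names=tuple(names), ward_cov=wc, hospital_var=None,
        ward_effects=ward_effects, hospital_effects=None, random_slope=slope,
        covariates=tuple(covariates), acceptance={},
    )


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([5.0] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auc([0.1, 0.2], [1, 1])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.all() or not labels.any():
            return
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_roc_trapezoid_equals_midrank(self, rng):
        scores = np.round(rng.random(300), 2)
        labels = (rng.random(300) < 0.3).astype(int)
        curve = roc_curve(scores, labels)
        area = np.trapezoid(curve["tpr"], curve["fpr"])
        assert area == pytest.approx(auc(scores, labels), abs=1e-12)
        assert curve.iloc[-1]["fpr"] == 1.0 and curve.iloc[-1]["tpr"] == 1.0


class TestHanleyMcNeil:
    def test_perfect_auc_has_zero_se(self):
        assert hanley_mcneil_se(1.0, 10, 20) == 0.0

    def test_direct_substitution_minimal_counts(self):
        # A=0.5: Q1=Q2=1/3, var = 0.25/1 = 0.25
        assert hanley_mcneil_se(0.5, 1, 1) == pytest.approx(0.5)

    def test_monotone_in_sample_size(self):
        ses = [hanley_mcneil_se(0.8, n, 50) for n in (5, 20, 100, 500)]
        assert all(a > b for a, b in zip(ses, ses[1:]))


class TestCompareAucs:
    def test_identical_scores_null_result(self, rng):
        s = rng.random(200)
        y = (rng.random(200) < 0.4).astype(int)
        res = compare_aucs(s, s, y)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(300), rng.random(300)
        y = (rng.random(300) < 0.3).astype(int)
        r1 = compare_aucs(a, b, y)
        r2 = compare_aucs(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_informative_vs_random_large_sample(self, rng):
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        good = y + 0.01 * rng.random(n)  # perfectly separating
        noise = rng.random(n)
        res = compare_aucs(good, noise, y)
        assert res.auc_a == 1.0
        assert res.p < 1e-6

    def test_hanley_mcneil_engine(self, rng):
        n = 500
        y = (rng.random(n) < 0.3).astype(int)
        x = rng.random(n)
        a = y * 0.5 + x * 0.5
        b = y * 0.3 + x * 0.7
        res = compare_aucs(a, b, y, engine="hanley-mcneil")
        assert res.engine == "hanley-mcneil"
        assert abs(res.r) <= 1.0
        assert res.se_a == pytest.approx(
            hanley_mcneil_se(res.auc_a, int(y.sum()), int((1 - y).sum()))
        )

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            compare_aucs([0.1, 0.2], [0.3], [0, 1])


class TestSir:
    def test_ratio_orientation(self):
        assert sir(10, 10.0) == 1.0
        assert sir(0, 4.2) == 0.0
        assert sir(12, 6.0) == 2.0  # above 1: more SSI than case-mix predicts

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            sir(3, 0.0)

    def test_ml_training_identity(self):
        """Overall SIR of an ML logistic model on its own training data is 1."""
        cohort = make_cohort(
            intercept=-2.0, ward_var=0.0,
            beta={"asa_gt2": 0.9}, prevalences={"asa_gt2": 0.3}, seed=44,
        )
        X, _, _ = build_design(cohort.df, ("asa_gt2",))
        y = cohort.df["ssi"].to_numpy(float)
        beta, _ = ml_logistic(X, y)
        probs = expit(X @ beta)
        results = sir_by_ward(cohort, probs)
        overall = [r for r in results if r.scope == "overall"][0]
        assert overall.sir == pytest.approx(1.0, abs=1e-5)
        assert overall.observed == int(y.sum())


class TestPredictProb:
    def test_null_model_predicts_half(self, tiny_cohort):
        draws = fake_draws([0.0], ["intercept"], [])
        probs = predict_prob(draws, tiny_cohort, "zero")
        np.testing.assert_allclose(probs, 0.5)

    def test_training_policy_manual_linear_predictor(self, tiny_cohort):
        wid = tiny_cohort.df["ward_id"].iloc[0]
        draws = fake_draws(
            [-1.0, 0.5], ["intercept", "asa_gt2"], ["asa_gt2"],
            ward_ids=[wid], ward_cov=[0.5], ward_u0=[0.7],
        )
        probs = predict_prob(draws, tiny_cohort, "training")
        x = tiny_cohort.df["asa_gt2"].to_numpy(float)
        in_ward = (tiny_cohort.df["ward_id"] == wid).to_numpy()
        expected = expit(-1.0 + 0.5 * x + 0.7 * in_ward)
        np.testing.assert_allclose(probs, expected)

    def test_unknown_ward_contributes_zero_under_training(self, tiny_cohort):
        draws = fake_draws(
            [-1.0], ["intercept"], [],
            ward_ids=["not-a-ward"], ward_cov=[0.5], ward_u0=[2.0],
        )
        probs = predict_prob(draws, tiny_cohort, "training")
        np.testing.assert_allclose(probs, expit(-1.0))

    def test_covariate_mismatch_rejected(self, tiny_cohort):
        draws = fake_draws([0.0, 1.0], ["intercept", "nothere"], ["asa_gt2"])
        with pytest.raises(ValueError, match="match"):
            predict_prob(draws, tiny_cohort, "zero")


class TestEstimateWardEffects:
    def test_vanishing_covariance_shrinks_to_zero(self, tiny_cohort):
        eff = estimate_ward_effects(np.array([-1.0]), [[1e-10]], tiny_cohort)
        assert np.abs(eff["u0"]).max() < 1e-5

    def test_large_ward_large_variance_near_ml_offset(self):
        cohort = make_cohort(
            n_hospitals=1, wards_per_hospital=1, patients_per_ward=4000,
            intercept=-1.2, ward_var=0.0, seed=5,
        )
        eff = estimate_ward_effects(np.array([0.0]), [[100.0]], cohort)
        # with a nearly flat prior the mode is the ward's ML intercept
        p = cohort.df["ssi"].mean()
        assert eff["u0"].iloc[0] == pytest.approx(np.log(p / (1 - p)), abs=0.01)

    def test_empirical_bayes_beats_zero_policy_in_expectation(self):
        """With real ward heterogeneity, EB ward effects lower the log-loss."""
        wins = 0
        for rep in range(20):
            cohort = make_cohort(
                n_hospitals=10, wards_per_hospital=3, patients_per_ward=80,
                intercept=-2.0, ward_var=1.0, seed=100 + rep,
            )
            draws = fake_draws(
                [-2.0], ["intercept"], [],
                ward_ids=sorted(cohort.df["ward_id"].unique()),
                ward_cov=[1.0],
                ward_u0=np.zeros(cohort.n_wards),
            )
            y = cohort.df["ssi"].to_numpy(float)
            ll = {}
            for policy in ("zero", "empirical_bayes"):
                p = np.clip(predict_prob(draws, cohort, policy), 1e-12, 1 - 1e-12)
                ll[policy] = np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            if ll["empirical_bayes"] >= ll["zero"]:
                wins += 1
        assert wins >= 17  # better on average, allowing a few tie-ish replicates
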