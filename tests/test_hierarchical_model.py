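"""Likelihood, sampler and screening behavior."""

import numpy as np
import pytest
from scipy.special import expit

from conftest import make_cohort, records_cohort
from ssiml.hierarchical_model import (
    McmcSettings,
    ModelSpec,
    coef_p,
    fit_mcmc,
    fit_model1_empty,
    fit_model2_intercept,
    fit_model3_slope,
    load_draws,
    log_likelihood,
    ml_logistic,
    save_draws,
    test_level_variance,
    univariate_screen,
)

SHORT = McmcSettings(burn_in=500, iterations=3000, thin=5, seed=3)


class TestLogLikelihood:
    def test_null_parameters_give_n_log_half(self, tiny_cohort):
        n = tiny_cohort.n_patients
        wards = {w: 0.0 for w in tiny_cohort.df["ward_id"].unique()}
        ll = log_likelihood([0.0], wards, None, tiny_cohort)
        assert ll == pytest.approx(n * np.log(0.5))

    def test_single_record_direct_evaluation(self):
        cohort = records_cohort(
            [{"hospital_id": "H1", "ward_id": "W1", "ssi": 1}]
        )
        ll = log_likelihood([2.0], {"W1": 0.0}, None, cohort)
        assert ll == pytest.approx(np.log(expit(2.0)))

    def test_permutation_invariance(self, tiny_cohort, rng):
        from ssiml.synthetic_cohort import CohortTable

        wards = {w: 0.1 for w in tiny_cohort.df["ward_id"].unique()}
        perm = rng.permutation(len(tiny_cohort.df))
        shuffled = CohortTable(tiny_cohort.df.iloc[perm].reset_index(drop=True))
        a = log_likelihood([-1.0, 0.3], wards, None, tiny_cohort, ("asa_gt2",))
        b = log_likelihood([-1.0, 0.3], wards, None, shuffled, ("asa_gt2",))
        assert a == pytest.approx(b)

    def test_unknown_ward_raises(self, tiny_cohort):
        with pytest.raises(KeyError, match="ward"):
            log_likelihood([0.0], {"nope": 0.0}, None, tiny_cohort)


class TestCoefP:
    def test_symmetric_draws_near_one(self, rng):
        assert coef_p(rng.normal(0, 1, 10_000)) > 0.9

    def test_one_sided_floor(self):
        assert coef_p(np.abs(np.random.default_rng(0).normal(size=500)) + 0.01) == 2 / 500

    def test_normal_tail_closed_form(self, rng):
        draws = rng.normal(1.0, 1.0, 200_000)
        assert coef_p(draws) == pytest.approx(0.3173, abs=0.01)


class TestSampler:
    def test_single_level_limit_matches_ml_glm(self):
        """With no random effects the posterior means equal ML estimates."""
        import statsmodels.api as sm

        cohort = make_cohort(
            n_hospitals=5,
            wards_per_hospital=2,
            patients_per_ward=100,
            intercept=-1.0,
            ward_var=0.0,
            beta={"asa_gt2": 0.8, "ambulatory": -0.7},
            prevalences={"asa_gt2": 0.3, "ambulatory": 0.3},
            seed=12,
        )
        spec = ModelSpec(
            covariates=("asa_gt2", "ambulatory"),
            levels=(),
            mcmc=McmcSettings(burn_in=1000, iterations=9000, thin=4, seed=5),
        )
        draws, _ = fit_mcmc(spec, cohort)
        X = np.column_stack(
            [
                np.ones(cohort.n_patients),
                cohort.df["asa_gt2"].to_numpy(float),
                cohort.df["ambulatory"].to_numpy(float),
            ]
        )
        y = cohort.df["ssi"].to_numpy(float)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for j in range(3):
            post_mean = draws.beta[:, j].mean()
            post_sd = draws.beta[:, j].std()
            assert abs(post_mean - glm.params[j]) < 2 * post_sd

    def test_seed_determinism(self, tiny_cohort):
        spec = ModelSpec(covariates=("asa_gt2",), levels=("ward",), mcmc=SHORT)
        d1, _ = fit_mcmc(spec, tiny_cohort)
        d2, _ = fit_mcmc(spec, tiny_cohort)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.ward_cov, d2.ward_cov)

    def test_draw_count_and_psd_constraint(self, tiny_cohort):
        spec = ModelSpec(
            covariates=("followup_ge15",),
            levels=("ward",),
            random_slope="followup_ge15",
            mcmc=SHORT,
        )
        cohort = make_cohort(
            prevalences={"followup_ge15": 0.6}, slope_cov=(0.0, 0.3), seed=8
        )
        draws, _ = fit_mcmc(spec, cohort)
        assert draws.n_draws == (3000 - 500) // 5
        wc = draws.ward_cov
        assert (wc[:, 0] > 0).all() and (wc[:, 2] >= 0).all()
        assert (np.abs(wc[:, 1]) <= np.sqrt(wc[:, 0] * wc[:, 2]) + 1e-12).all()

    def test_zero_variance_data_concentrates_near_zero(self):
        cohort = make_cohort(
            n_hospitals=25, wards_per_hospital=4, patients_per_ward=50,
            intercept=-2.0, ward_var=0.0, seed=31,
        )
        draws, summ = fit_model1_empty(
            cohort, levels=("ward",),
            mcmc=McmcSettings(burn_in=1000, iterations=6000, thin=5, seed=2),
        )
        lower = np.percentile(draws.ward_cov[:, 0], 2.5)
        assert lower < 0.05

    def test_constant_covariate_rejected(self, tiny_cohort):
        from ssiml.synthetic_cohort import CohortTable

        df = tiny_cohort.df.copy()
        df["asa_gt2"] = 0
        with pytest.raises(ValueError, match="constant"):
            fit_mcmc(
                ModelSpec(covariates=("asa_gt2",), levels=("ward",), mcmc=SHORT),
                CohortTable(df),
            )

    def test_empty_model_has_single_fixed_effect(self, tiny_cohort):
        draws, summ = fit_model1_empty(tiny_cohort, levels=("ward",), mcmc=SHORT)
        assert draws.beta_names == ("intercept",)
        assert len(summ.coefficients) == 1
        assert summ.variance_components["component"].tolist() == ["ward_var_intercept"]

    def test_three_level_fit_reports_hospital_variance(self):
        cohort = make_cohort(hospital_variance=0.5, seed=13)
        draws, summ = fit_model1_empty(cohort, mcmc=SHORT)
        assert draws.hospital_var is not None
        assert "hospital_var" in summ.variance_components["component"].tolist()

    def test_nested_model2_model3_agreement_without_slope_variance(self):
        """On data with no slope heterogeneity both models agree on beta."""
        cohort = make_cohort(
            n_hospitals=20, wards_per_hospital=3, patients_per_ward=60,
            intercept=-2.0, ward_var=0.4,
            beta={"followup_ge15": -0.8, "asa_gt2": 0.7},
            prevalences={"followup_ge15": 0.6, "asa_gt2": 0.25},
            seed=19,
        )
        covs = ("asa_gt2", "followup_ge15")
        st2 = McmcSettings(burn_in=1000, iterations=7000, thin=5, seed=4)
        d2, _ = fit_model2_intercept(cohort, covs, mcmc=st2)
        d3, _ = fit_model3_slope(cohort, covs, "followup_ge15", mcmc=st2)
        for j in range(len(d2.beta_names)):
            se = max(d2.beta[:, j].std(), d3.beta[:, j].std())
            assert abs(d2.beta[:, j].mean() - d3.beta[:, j].mean()) < 3 * se

    def test_doubling_iterations_stable_posterior_means(self):
        cohort = make_cohort(seed=23, prevalences={"asa_gt2": 0.3})
        base = dict(covariates=("asa_gt2",), levels=("ward",))
        d1, _ = fit_mcmc(
            ModelSpec(**base, mcmc=McmcSettings(burn_in=1000, iterations=5000, thin=4, seed=6)),
            cohort,
        )
        d2, _ = fit_mcmc(
            ModelSpec(**base, mcmc=McmcSettings(burn_in=1000, iterations=9000, thin=4, seed=6)),
            cohort,
        )
        for j in range(d1.beta.shape[1]):
            mcse = d1.beta[:, j].std() / np.sqrt(max(_ess(d1.beta[:, j]), 4))
            assert abs(d1.beta[:, j].mean() - d2.beta[:, j].mean()) < 4 * mcse

    def test_posterior_archive_roundtrip(self, tiny_cohort, tmp_path):
        spec = ModelSpec(covariates=("asa_gt2",), levels=("ward",), mcmc=SHORT)
        draws, _ = fit_mcmc(spec, tiny_cohort)
        save_draws(draws, tmp_path / "post.npz")
        back = load_draws(tmp_path / "post.npz")
        np.testing.assert_array_equal(back.beta, draws.beta)
        np.testing.assert_array_equal(back.ward_cov, draws.ward_cov)
        assert back.beta_names == draws.beta_names
        assert back.ward_effects.equals(draws.ward_effects)


def _ess(x):
    import arviz as az
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[None, :]))


class TestLevelVarianceTest:
    def test_identical_levels_give_p_one(self, tiny_cohort):
        assert test_level_variance(tiny_cohort, ("ward",), ("ward",)) == 1.0

    def test_reduced_not_subset_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="subset"):
            test_level_variance(tiny_cohort, ("ward",), ("ward", "hospital"))

    def test_power_against_large_hospital_variance(self):
        cohort = make_cohort(
            n_hospitals=50, wards_per_hospital=4, patients_per_ward=50,
            intercept=-2.0, ward_var=0.3, hospital_variance=1.0, seed=3,
        )
        p = test_level_variance(cohort, ("ward", "hospital"), ("ward",))
        assert p < 0.01

    def test_detects_ward_variance(self):
        cohort = make_cohort(
            n_hospitals=40, wards_per_hospital=4, patients_per_ward=60,
            intercept=-2.0, ward_var=1.0, seed=4,
        )
        p = test_level_variance(cohort, ("ward",), ())
        assert p < 1e-6


class TestUnivariateScreen:
    def test_informative_covariate_retained(self):
        cohort = make_cohort(
            n_hospitals=25, wards_per_hospital=4, patients_per_ward=200,
            intercept=-3.0, ward_var=0.3,
            beta={"asa_gt2": np.log(2.0)},
            prevalences={"asa_gt2": 0.3, "gender_female": 0.5},
            seed=6,
        )
        assert cohort.n_patients == 20_000
        retained = univariate_screen(cohort, ("asa_gt2",), alpha=0.20)
        assert retained == ["asa_gt2"]

    def test_alpha_one_retains_everything(self, tiny_cohort):
        cands = ("asa_gt2", "gender_female")
        retained = univariate_screen(tiny_cohort, cands, alpha=1.01, mcmc=SHORT)
        assert retained == list(cands)
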