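"""Imputation fits, stochastic assignment, prevalence recovery and OSTA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from fraxpath.imputation import (COVARIATE_SETS, FactorModel, ImputationModel,
                                 MissingCovariateError, factor_seed,
                                 fit_imputation_model, impute_dichotomous,
                                 impute_tscore, osta_index, osta_validate,
                                 prevalence_report)
from fraxpath.synthetic import CohortSpec, generate_reference_cohort


@pytest.fixture(scope="module")
def big_reference():
    return generate_reference_cohort(50_000, seed=11)


@pytest.fixture(scope="module")
def fitted(big_reference):
    return fit_imputation_model(big_reference)


def intercept_only_model(factor, p, covariates=None):
    return ImputationModel({factor: FactorModel(
        factor, covariates or COVARIATE_SETS.get(factor, ()),
        np.array([logit(p)]) if 0 < p < 1 else np.array([np.inf * (2 * p - 1)]),
        intercept_only=True)})


class TestFit:
    def test_recovers_generating_logistic_coefficients(self, big_reference,
                                                       fitted):
        """Parameter-recovery harness: truth from the generator's equations."""
        import statsmodels.api as sm
        from fraxpath.synthetic import (AGE_CENTER, BMI_CENTER,
                                        solve_structural_model)
        struct = solve_structural_model(CohortSpec())
        truth = {
            "parental_hip_fracture": {
                "intercept": struct.parental_intercept
                - 0.02 * AGE_CENTER + 0.0,
                "age": 0.02, "prior_fracture": 0.3},
            "rheumatoid_arthritis": {
                # generator centres bmi at the cohort mean and sex_female at 1
                "intercept": struct.ra_intercept + 0.04 * BMI_CENTER - 0.6,
                "sex_female": 0.6, "bmi": -0.04, "prior_fracture": 0.4},
        }
        for factor, true_coef in truth.items():
            fm = fitted[factor]
            assert not fm.intercept_only
            # refit to obtain standard errors on the same design
            from fraxpath.imputation import _design_matrix
            X = _design_matrix(big_reference, fm.covariates, factor)
            res = sm.Logit(big_reference[factor].to_numpy(float), X).fit(
                disp=False)
            se = res.bse
            names = ["intercept", *fm.covariates]
            for i, name in enumerate(names):
                assert abs(fm.coef[i] - true_coef[name]) < 3 * se[i], \
                    f"{factor}:{name}"

    def test_tscore_residual_sd_recovered(self, fitted):
        from fraxpath.synthetic import solve_structural_model
        true_sd = solve_structural_model(CohortSpec()).tscore_noise_sd
        assert fitted["fn_tscore"].residual_sd == pytest.approx(true_sd,
                                                                rel=0.05)

    def test_null_effect_covariates_near_zero(self, big_reference, fitted):
        """T-score truth has no prior-fracture or smoking effect; the fitted
        slopes must be within noise of zero."""
        import statsmodels.api as sm
        from fraxpath.imputation import _design_matrix
        fm = fitted["fn_tscore"]
        X = _design_matrix(big_reference, fm.covariates, "fn_tscore")
        se = sm.OLS(big_reference["fn_tscore"].to_numpy(float), X).fit().bse
        for cov in ("prior_fracture", "current_smoking"):
            i = 1 + fm.covariates.index(cov)
            assert abs(fm.coef[i]) < 3 * se[i]

    def test_covariate_sets_are_protocol_fixed(self, fitted):
        assert fitted["parental_hip_fracture"].covariates == (
            "age", "prior_fracture")
        assert fitted["glucocorticoids"].covariates == (
            "age", "sex_female", "bmi")
        assert fitted["rheumatoid_arthritis"].covariates == (
            "sex_female", "bmi", "prior_fracture")
        assert fitted["fn_tscore"].covariates == (
            "age", "bmi", "prior_fracture", "current_smoking")

    def test_degenerate_factor_falls_back_to_intercept_only(self):
        ref = generate_reference_cohort(2000, seed=5)
        ref["parental_hip_fracture"] = 0
        model = fit_imputation_model(ref)
        assert model["parental_hip_fracture"].intercept_only

    def test_small_reference_rejected(self):
        ref = generate_reference_cohort(2000, seed=5).head(50)
        with pytest.raises(ValueError):
            fit_imputation_model(ref)

    def test_yaml_round_trip(self, fitted, tmp_path):
        path = tmp_path / "model.yaml"
        fitted.to_yaml(path)
        back = ImputationModel.from_yaml(path)
        for name, fm in fitted.factors.items():
            np.testing.assert_allclose(back[name].coef, fm.coef, rtol=1e-12)
            assert back[name].covariates == fm.covariates


class TestImputeDichotomous:
    def make_cohort(self, n):
        rng = np.random.default_rng(3)
        return pd.DataFrame({
            "id": np.arange(n), "age": rng.uniform(50, 85, n),
            "sex": "female", "bmi": rng.uniform(18, 30, n),
            "prior_fracture": rng.integers(0, 2, n),
            "current_smoking": rng.integers(0, 2, n),
            "parental_hip_fracture": np.nan, "fn_tscore": np.nan})

    @pytest.mark.parametrize("p,expect", [(0.0, 0), (1.0, 5000)])
    def test_boundary_probabilities(self, p, expect):
        cohort = self.make_cohort(5000)
        model = intercept_only_model("parental_hip_fracture", p)
        out = impute_dichotomous(cohort, model, "parental_hip_fracture", 1)
        assert out["parental_hip_fracture"].sum() == expect

    def test_intercept_only_prevalence_within_binomial_noise(self):
        n, p = 29_323, 0.066
        cohort = self.make_cohort(n)
        model = intercept_only_model("parental_hip_fracture", p)
        out = impute_dichotomous(cohort, model, "parental_hip_fracture", 9)
        count = out["parental_hip_fracture"].sum()
        assert abs(count - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_same_seed_identical_different_seed_differs(self, fitted):
        cohort = self.make_cohort(4000)
        a = impute_dichotomous(cohort, fitted, "parental_hip_fracture", 5)
        b = impute_dichotomous(cohort, fitted, "parental_hip_fracture", 5)
        c = impute_dichotomous(cohort, fitted, "parental_hip_fracture", 6)
        assert a["parental_hip_fracture"].equals(b["parental_hip_fracture"])
        assert not a["parental_hip_fracture"].equals(c["parental_hip_fracture"])

    def test_missing_covariate_error_names_rows(self, fitted):
        cohort = self.make_cohort(10)
        cohort.loc[3, "age"] = np.nan
        with pytest.raises(MissingCovariateError, match="age"):
            impute_dichotomous(cohort, fitted, "parental_hip_fracture", 1)

    def test_factor_streams_independent(self):
        assert factor_seed(1, "parental_hip_fracture") != factor_seed(
            1, "rheumatoid_arthritis")
        assert factor_seed(1, "fn_tscore") < 2**31


class TestImputeTscore:
    def linear_model(self, coef, sd):
        return ImputationModel({"fn_tscore": FactorModel(
            "fn_tscore", COVARIATE_SETS["fn_tscore"], np.asarray(coef, float),
            residual_sd=sd)})

    def test_noise_off_exact_linear_combination(self):
        model = self.linear_model([1.0, -0.05, 0.03, -0.3, -0.1], 0.8)
        cohort = pd.DataFrame({
            "age": [60.0, 70.0, 0.0], "bmi": [25.0, 20.0, 0.0],
            "prior_fracture": [0, 1, 0], "current_smoking": [1, 0, 0],
            "fn_tscore": np.nan})
        out = impute_tscore(cohort, model, rng_seed=1, noise=False)
        expected = [1 - 0.05 * 60 + 0.03 * 25 - 0.1,
                    1 - 0.05 * 70 + 0.03 * 20 - 0.3,
                    1.0]  # all-zero covariates -> intercept exactly
        np.testing.assert_allclose(out["fn_tscore"], expected, rtol=1e-12)

    def test_noise_on_variance_decomposition(self):
        rng = np.random.default_rng(12)
        n = 60_000
        cohort = pd.DataFrame({
            "age": rng.normal(62, 8, n), "bmi": rng.normal(23, 3.6, n),
            "prior_fracture": 0, "current_smoking": 0, "fn_tscore": np.nan})
        sd = 0.8
        model = self.linear_model([0.0, -0.05, 0.03, 0.0, 0.0], sd)
        out = impute_tscore(cohort, model, rng_seed=2, noise=True)
        explained = (0.05 * 8) ** 2 + (0.03 * 3.6) ** 2
        assert out["fn_tscore"].std() == pytest.approx(
            np.sqrt(explained + sd ** 2), rel=0.02)


class TestPrevalenceReport:
    def test_identical_cohorts_zero_difference(self, big_reference):
        rep = prevalence_report(big_reference, big_reference)
        assert np.allclose(rep["abs_difference"], 0.0)

    def test_self_consistency_after_imputation(self, big_reference, fitted):
        target = big_reference.copy()
        for f in ("parental_hip_fracture", "glucocorticoids",
                  "rheumatoid_arthritis"):
            target[f] = np.nan
            target = impute_dichotomous(target, fitted, f, rng_seed=21)
        rep = prevalence_report(target, big_reference)
        assert (rep["abs_difference"] < 0.01).all()

    def test_doubled_reference_prevalence_shows_offset(self, big_reference):
        doubled = big_reference.copy()
        p = doubled["rheumatoid_arthritis"].mean()
        flip = np.random.default_rng(1).random(len(doubled)) < p
        doubled["rheumatoid_arthritis"] = (
            doubled["rheumatoid_arthritis"].astype(bool) | flip).astype(int)
        rep = prevalence_report(big_reference, doubled,
                                factors=("rheumatoid_arthritis",))
        assert rep["abs_difference"].iloc[0] == pytest.approx(p, abs=0.005)


class TestOsta:
    def test_index_arithmetic(self):
        assert osta_index(60.0, 60.0) == 0.0
        assert osta_index(45.0, 75.0) == -6.0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        n = 5000
        cohort = pd.DataFrame({
            "age": rng.uniform(50, 85, n),
            "weight": rng.normal(55, 9, n),
            "bmi": rng.normal(23, 3.5, n),
            "fn_tscore": rng.normal(-1.9, 0.9, n)})
        res = osta_validate(cohort, cutoff=-1.0)
        idx = 0.2 * (cohort["weight"] - cohort["age"])
        sp, cp = idx < -1.0, cohort["fn_tscore"] <= -2.5
        sens = 100 * (sp & cp).sum() / cp.sum()
        spec = 100 * (~sp & ~cp).sum() / (~cp).sum()
        assert res["sensitivity_pct"] == pytest.approx(sens)
        assert res["specificity_pct"] == pytest.approx(spec)

    def test_no_condition_positives_undefined_sensitivity(self):
        cohort = pd.DataFrame({"age": [60.0], "weight": [70.0],
                               "bmi": [25.0], "fn_tscore": [0.0]})
        res = osta_validate(cohort)
        assert not res["sensitivity_defined"]
        assert np.isnan(res["sensitivity_pct"])

    def test_weight_reconstructed_from_bmi_when_absent(self):
        rng = np.random.default_rng(8)
        cohort = pd.DataFrame({
            "age": rng.uniform(55, 80, 2000),
            "bmi": rng.normal(23, 3.5, 2000),
            "fn_tscore": rng.normal(-1.9, 0.9, 2000)})
        res = osta_validate(cohort, seed=4)
        assert 0 <= res["specificity_pct"] <= 100
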