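import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oracle_utils import fit_ordinal_bruteforce
from pgspart import assoc
from pgspart.exceptions import (DegenerateDataError, InputDataError,
                                StructureError)


def simulate_ordinal(n, beta, rng, n_cov=0, thresholds=(-1.0, 0.2, 1.3)):
    """Draw grades from a proportional-odds model with known slope."""
    x = rng.standard_normal(n)
    covs = rng.standard_normal((n, n_cov)) if n_cov else None
    lin = beta * x
    if covs is not None:
        lin = lin + covs @ np.full(n_cov, 0.2)
    u = lin + rng.logistic(size=n)
    grades = np.searchsorted(np.asarray(thresholds), u)
    cov_df = (pd.DataFrame(covs, columns=[f"c{i}" for i in range(n_cov)])
              if covs is not None else None)
    return grades, x, cov_df


class TestOrdinalFit:
    def test_matches_bruteforce_mle_on_small_fixture(self, rng):
        grades, x, _ = simulate_ordinal(30, 0.8, rng)
        fit = assoc.fit_ordinal(grades, x, school_mode="none")
        beta_o, thresh_o, nll_o = fit_ordinal_bruteforce(
            grades, x.reshape(-1, 1))
        assert fit.beta == pytest.approx(beta_o[0], abs=1e-4)
        assert -fit.llf == pytest.approx(nll_o, abs=1e-6)
        model_thresh = fit._fit.model.transform_threshold_params(
            np.asarray(fit._fit.params))[1:-1]
        np.testing.assert_allclose(model_thresh, thresh_o, atol=1e-4)

    def test_category_reversal_inverts_odds_ratio(self, rng):
        grades, x, _ = simulate_ordinal(400, 0.5, rng)
        fit = assoc.fit_ordinal(grades, x, school_mode="none")
        rev = assoc.fit_ordinal(grades.max() - grades, x,
                                school_mode="none")
        assert rev.or_ == pytest.approx(1.0 / fit.or_, rel=1e-4)

    def test_positive_beta_means_better_grades(self, rng):
        grades, x, _ = simulate_ordinal(3000, 0.7, rng)
        fit = assoc.fit_ordinal(grades, x, school_mode="none")
        assert fit.beta > 0
        assert fit.or_ > 1
        lo, hi = fit.ci
        assert lo == pytest.approx(np.exp(fit.beta - assoc.Z95 * fit.se))
        assert hi == pytest.approx(np.exp(fit.beta + assoc.Z95 * fit.se))

    def test_binary_collapse_sign_agrees_with_logistic(self, rng):
        grades, x, _ = simulate_ordinal(800, -0.6, rng)
        collapsed = (grades >= 2).astype(int)
        fit = assoc.fit_ordinal(collapsed, x, school_mode="none")
        logit = sm.Logit(collapsed, sm.add_constant(x)).fit(disp=0)
        assert np.sign(fit.beta) == np.sign(logit.params[1])
        assert fit.beta == pytest.approx(logit.params[1], rel=1e-3)

    def test_single_category_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            assoc.fit_ordinal(np.ones(50, dtype=int),
                              rng.standard_normal(50), school_mode="none")

    def test_quasi_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        grades = (x > 0).astype(int)  # perfectly separated
        with pytest.raises(Exception):
            assoc.fit_ordinal(grades, x, school_mode="none")


class TestNagelkerke:
    def test_identical_fits_give_zero_delta(self, rng):
        grades, x, covs = simulate_ordinal(200, 0.4, rng, n_cov=2)
        fit = assoc.fit_ordinal(grades, x, covariates=covs,
                                school_mode="none")
        assert assoc.delta_nagelkerke(fit, fit) == 0.0

    def test_matches_closed_form_hand_computation(self):
        # 3-category toy with specified log-likelihoods
        n = 100
        ll0 = -109.861228866811  # 100 * log(1/3) with equal categories
        ll_red = -105.0
        ll_full = -98.0
        r2 = assoc.nagelkerke_r2
        expected = ((1 - np.exp(2 * (ll0 - ll_full) / n))
                    / (1 - np.exp(2 * ll0 / n))
                    - (1 - np.exp(2 * (ll0 - ll_red) / n))
                    / (1 - np.exp(2 * ll0 / n)))
        got = r2(ll_full, ll0, n) - r2(ll_red, ll0, n)
        assert got == pytest.approx(expected, abs=1e-12)
        fit_full = assoc.AssocResult(term="pgs", beta=1, se=1, z=1, p=0.5,
                                     n=n, llf=ll_full, ll_null=ll0,
                                     exog_names=("a", "pgs"))
        fit_red = assoc.AssocResult(term="(none)", beta=1, se=1, z=1, p=0.5,
                                    n=n, llf=ll_red, ll_null=ll0,
                                    exog_names=("a",))
        assert assoc.delta_nagelkerke(fit_full, fit_red) == pytest.approx(
            expected, abs=1e-12)

    def test_non_nested_models_rejected(self):
        a = assoc.AssocResult(term="pgs", beta=1, se=1, z=1, p=0.5, n=10,
                              llf=-5, ll_null=-8, exog_names=("pgs",))
        b = assoc.AssocResult(term="x", beta=1, se=1, z=1, p=0.5, n=10,
                              llf=-6, ll_null=-8, exog_names=("x",))
        with pytest.raises(StructureError):
            assoc.delta_nagelkerke(a, b)

    def test_delta_invariant_to_affine_covariate_recoding(self, rng):
        grades, x, covs = simulate_ordinal(500, 0.4, rng, n_cov=2)
        fit1 = assoc.fit_ordinal(grades, x, covariates=covs,
                                 school_mode="none", compute_delta_r2=True)
        recoded = covs * 3.0 - 1.7
        fit2 = assoc.fit_ordinal(grades, x, covariates=recoded,
                                 school_mode="none", compute_delta_r2=True)
        assert fit1.delta_r2 == pytest.approx(fit2.delta_r2, abs=1e-6)


class TestQuintiles:
    def test_equal_split_of_1000(self, rng):
        q = assoc.make_quintiles(rng.standard_normal(1000))
        assert list(np.bincount(q)[1:]) == [200] * 5

    def test_constant_pgs_rejected(self):
        with pytest.raises(DegenerateDataError, match="ties"):
            assoc.make_quintiles(np.ones(100))

    def test_top_quintile_strongest_under_positive_effect(self, rng):
        grades, x, _ = simulate_ordinal(2500, 0.8, rng)
        tab = assoc.quintile_contrast(grades, x, school_mode="none")
        ors = tab.set_index("quintile")["OR"]
        assert ors[5] > ors[2] > 1.0
        assert tab["p"].iloc[-1] < 1e-6


class TestPredictedProbabilities:
    def test_probabilities_sum_to_one(self, rng):
        grades, x, covs = simulate_ordinal(600, 0.5, rng, n_cov=2)
        fit = assoc.fit_ordinal(grades, x, covariates=covs,
                                school_mode="none")
        curves = assoc.predicted_probabilities(fit, np.linspace(-3, 3, 13))
        probs = curves.drop(columns="pgs").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_null_effect_gives_flat_curves(self, rng):
        grades, x, _ = simulate_ordinal(600, 0.0, rng)
        fit = assoc.fit_ordinal(grades, x, school_mode="none")
        # force the slope to exactly zero to isolate curve behaviour
        params = fit._fit.params.copy()
        params.iloc[0] = 0.0
        fit._fit.params = params
        curves = assoc.predicted_probabilities(fit, np.linspace(-3, 3, 7))
        probs = curves.drop(columns="pgs").to_numpy()
        np.testing.assert_allclose(probs, probs[[0]].repeat(7, axis=0),
                                   atol=1e-12)

    def test_top_category_monotone_in_pgs(self, rng):
        grades, x, _ = simulate_ordinal(2000, 0.7, rng)
        fit = assoc.fit_ordinal(grades, x, school_mode="none")
        curves = assoc.predicted_probabilities(fit, np.linspace(-3, 3, 21))
        top = curves.iloc[:, -1].to_numpy()
        assert np.all(np.diff(top) > 0)


class TestLinearScale:
    def test_noiseless_recovery(self):
        x = np.linspace(-1.5, 1.5, 50)
        y = (1.0 + 0.5 * x) ** 2  # sqrt(y) = 1 + 0.5 x exactly (all > 0)
        fit = assoc.fit_linear_scale(y, x, school_mode="none")
        assert fit.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal(10)
        y = np.abs(rng.standard_normal(10)) + 0.1
        fit = assoc.fit_linear_scale(y, x, school_mode="none")
        design = np.column_stack([np.ones(10), x])
        coef = np.linalg.solve(design.T @ design, design.T @ np.sqrt(y))
        assert fit.beta == pytest.approx(coef[1], abs=1e-10)

    def test_negative_values_rejected(self, rng):
        with pytest.raises(InputDataError):
            assoc.fit_linear_scale(np.array([-1.0, 2.0, 3.0]),
                                   rng.standard_normal(3),
                                   school_mode="none")

    def test_permutation_null_calibration(self, rng):
        n_sig = 0
        reps = 100
        for _ in range(reps):
            x = rng.standard_normal(300)
            y = np.abs(rng.standard_normal(300))
            fit = assoc.fit_linear_scale(y, x, school_mode="none")
            n_sig += abs(fit.z) > 1.96
        assert n_sig / reps <= 0.07


class TestSchoolMode:
    def test_auto_uses_indicators_for_large_schools(self, rng):
        grades, x, _ = simulate_ordinal(400, 0.5, rng)
        school = np.repeat([0, 1, 2, 3], 100)
        fit = assoc.fit_ordinal(grades, x, school=school,
                                school_mode="auto")
        assert any(n.startswith("school_") for n in fit.exog_names)

    def test_auto_drops_indicators_for_thin_schools(self, rng):
        grades, x, _ = simulate_ordinal(60, 0.5, rng)
        school = np.arange(60) % 30  # 2 per school
        fit = assoc.fit_ordinal(grades, x, school=school,
                                school_mode="auto")
        assert not any(n.startswith("school_") for n in fit.exog_names)
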