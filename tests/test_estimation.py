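import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

from cigdemand.estimation import (
    fit_ols,
    fit_probit,
    fit_two_part,
    probit_loglik,
)
from cigdemand.synthetic import (
    consumption_matrix,
    default_dgp_params,
    generate_households,
    participation_matrix,
)


class TestProbitLoglik:
    def test_intercept_only_symmetric(self):
        X = np.ones((2, 1))
        assert probit_loglik([0.0], X, [1, 0]) == pytest.approx(2 * math.log(0.5))

    def test_empty_data(self):
        assert probit_loglik([0.5, -1.0], np.empty((0, 2)), []) == 0.0

    def test_matches_per_row_summation_oracle(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
        z = rng.integers(0, 2, 10)
        coef = np.array([0.3, -0.8, 1.1])
        # independent oracle: term-by-term summation with scalar normal CDF
        expected = 0.0
        for i in range(10):
            p = norm.cdf(float(X[i] @ coef))
            expected += math.log(p) if z[i] == 1 else math.log(1 - p)
        assert probit_loglik(coef, X, z) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="rows"):
            probit_loglik([0.0], np.ones((3, 1)), [1, 0])
        with pytest.raises(ValueError, match="coefficient length"):
            probit_loglik([0.0, 1.0], np.ones((2, 1)), [1, 0])

    def test_finite_for_extreme_index(self):
        X = np.ones((1, 1))
        assert np.isfinite(probit_loglik([50.0], X, [0]))


class TestFitProbit:
    def test_intercept_only_even_split(self):
        z = np.array([1, 0] * 50)
        fit = fit_probit(np.ones((100, 1)), z, terms=("const",))
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.participation_rate == 0.5

    def test_intercept_only_rare_nonparticipation(self):
        z = np.concatenate([np.ones(975), np.zeros(25)])
        fit = fit_probit(np.ones((1000, 1)), z, terms=("const",))
        assert fit.coefficients[0] == pytest.approx(1.959964, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_probit(np.ones((10, 1)), np.ones(10), terms=("const",))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2 * x])
        z = (x + rng.normal(size=100) > 0).astype(int)
        with pytest.raises(ValueError, match="collinear"):
            fit_probit(X, z, terms=("const", "x", "x2"))

    def test_separation_flagged_not_raised(self):
        x = np.linspace(-1, 1, 40)
        z = (x > 0).astype(int)  # perfectly separated
        X = np.column_stack([np.ones(40), x])
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_probit(X, z, terms=("const", "x"))
        assert not fit.converged

    def test_recovers_dgp_coefficients(self):
        p = default_dgp_params(3, n_per_quintile=50_000, seed=103)
        df = generate_households(p)
        fit = fit_probit(participation_matrix(df), df["smoke"].to_numpy())
        assert fit.converged
        z = np.abs(fit.coefficients - p.alpha) / fit.standard_errors
        assert z.max() < 3.0

    def test_fitted_beats_dgp_loglik(self, q3_params, q3_table):
        # maximizer property: the MLE cannot be worse than the true vector
        W = participation_matrix(q3_table)
        z = q3_table["smoke"].to_numpy()
        fit = fit_probit(W, z)
        assert probit_loglik(fit.coefficients, W, z) >= probit_loglik(
            q3_params.alpha, W, z
        )

    def test_price_shift_invariance(self, q3_table):
        # adding a constant to ln_price only moves the intercept
        W = participation_matrix(q3_table)
        z = q3_table["smoke"].to_numpy()
        fit = fit_probit(W, z)
        W2 = W.copy()
        j = fit.terms.index("ln_price")
        W2[:, j] += 2.0
        fit2 = fit_probit(W2, z)
        np.testing.assert_allclose(W @ fit.coefficients, W2 @ fit2.coefficients,
                                   atol=1e-5)

    def test_agrees_with_statsmodels(self, q3_table):
        sm = pytest.importorskip("statsmodels.api")
        W = participation_matrix(q3_table)
        z = q3_table["smoke"].to_numpy()
        ours = fit_probit(W, z)
        ref = sm.Probit(z, W).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)


class TestFitOLS:
    def test_noiseless_exact_interpolation(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(16, 0.5, 50)
        x2 = rng.normal(11, 0.3, 50)
        X = np.column_stack([np.ones(50), x1, x2])
        y = 7.9 + 0.039 * x1 - 0.389 * x2
        fit = fit_ols(X, y, terms=("const", "x1", "x2"))
        np.testing.assert_allclose(fit.coefficients, [7.9, 0.039, -0.389], atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        fit = fit_ols(X, np.full(30, 4.2), terms=("const", "x"))
        np.testing.assert_allclose(fit.coefficients, [4.2, 0.0], atol=1e-10)

    def test_residuals_orthogonal_to_design(self, q3_params, q3_table):
        smokers = q3_table[q3_table["smoke"] == 1]
        X = consumption_matrix(smokers)
        y = np.log(smokers["sticks_month"].to_numpy())
        fit = fit_ols(X, y)
        resid = y - X @ fit.coefficients
        np.testing.assert_allclose(X.T @ resid / len(y), 0.0, atol=1e-8)

    def test_recovers_price_coefficient(self):
        p = default_dgp_params(3, n_per_quintile=50_000, seed=104)
        df = generate_households(p)
        smokers = df[df["smoke"] == 1]
        fit = fit_ols(
            consumption_matrix(smokers), np.log(smokers["sticks_month"].to_numpy())
        )
        j = fit.terms.index("ln_price")
        assert abs(fit.coefficients[j] - p.beta[j]) < 3 * fit.standard_errors[j]

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        with pytest.raises(ValueError, match="dup"):
            fit_ols(X, np.arange(20.0), terms=("const", "dup1", "dup2"))

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="observations"):
            fit_ols(np.ones((2, 3)), np.zeros(2), terms=("a", "b", "c"))

    def test_agrees_with_statsmodels(self, q3_table):
        sm = pytest.importorskip("statsmodels.api")
        smokers = q3_table[q3_table["smoke"] == 1]
        X = consumption_matrix(smokers)
        y = np.log(smokers["sticks_month"].to_numpy())
        ours = fit_ols(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-8)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-8)
        assert ours.r_squared == pytest.approx(ref.rsquared)


class TestFitTwoPart:
    def test_part_two_design_rows(self, tiny_survey):
        smokers = tiny_survey[tiny_survey["smoke"] == 1]
        assert consumption_matrix(smokers).shape == (3, 11)

    def test_smokers_subset_of_households(self, q3_table):
        probit, ols = fit_two_part(q3_table, 3)
        assert ols.n < probit.n
        assert probit.n == len(q3_table)

    def test_missing_quintile_rejected(self, q3_table):
        with pytest.raises(ValueError, match="quintile 5"):
            fit_two_part(q3_table, 5)

    def test_q2_price_recovery(self):
        p = default_dgp_params(2, n_per_quintile=50_000, seed=102)
        df = generate_households(p)
        probit, ols = fit_two_part(df, 2)
        jp = probit.terms.index("ln_price")
        jo = ols.terms.index("ln_price")
        assert abs(probit.coefficients[jp] - (-0.086)) < 3 * probit.standard_errors[jp]
        assert abs(ols.coefficients[jo] - (-0.356)) < 3 * ols.standard_errors[jo]

    def test_mean_index_and_rate_populated(self, q3_table):
        probit, _ = fit_two_part(q3_table, 3)
        assert 0.0 < probit.participation_rate < 1.0
        assert probit.participation_rate == pytest.approx(q3_table["smoke"].mean())
        W = participation_matrix(q3_table)
        assert probit.mean_linear_index == pytest.approx(
            float(W.mean(axis=0) @ probit.coefficients)
        )

    def test_roundtrip_serialization(self, q3_table):
        probit, ols = fit_two_part(q3_table, 3)
        from cigdemand.estimation import OLSFit, ProbitFit

        p2 = ProbitFit.from_dict(probit.to_dict())
        o2 = OLSFit.from_dict(ols.to_dict())
        np.testing.assert_array_equal(p2.coefficients, probit.coefficients)
        np.testing.assert_array_equal(o2.coefficients, ols.coefficients)
        assert p2.terms == probit.terms
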