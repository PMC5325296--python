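import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from riparia.glm import (
    GlmFit,
    aicc,
    akaike_weights,
    all_subsets,
    confidence_set,
    explained_deviance,
    fit_glm,
    importance_and_average,
    multimodel_summary,
    qaicc,
)


def ols_reference(y, X):
    """Closed-form OLS with Gaussian ML log-likelihood (independent oracle)."""
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    n, p = design.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(design.T @ design)) * sigma2)
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    sigma2_ml = resid @ resid / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1)
    return beta, se, t, pvals, llf


def poisson_newton_reference(y, X):
    """Direct Newton optimisation of the Poisson log-likelihood."""
    design = np.column_stack([np.ones(len(y)), X])

    def negll(beta):
        eta = design @ beta
        return -(y @ eta - np.exp(eta).sum())

    def grad(beta):
        return -design.T @ (y - np.exp(design @ beta))

    def hess(beta):
        mu = np.exp(design @ beta)
        return design.T @ (design * mu[:, None])

    res = optimize.minimize(
        negll, np.zeros(design.shape[1]), jac=grad, hess=hess, method="trust-ncg", tol=1e-12
    )
    return res.x


class TestGaussianFit:
    def test_matches_closed_form_ols(self, rng):
        for _ in range(20):
            n = rng.integers(8, 30)
            X = rng.normal(size=(n, 2))
            y = 1.0 + X @ np.array([0.5, -2.0]) + rng.normal(size=n)
            fit = fit_glm(y, pd.DataFrame(X, columns=["a", "b"]))
            beta, se, t, pvals, llf = ols_reference(y, X)
            assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-8)
            assert fit.bse.to_numpy() == pytest.approx(se, abs=1e-8)
            assert fit.statistics.to_numpy() == pytest.approx(t, abs=1e-8)
            assert fit.pvalues.to_numpy() == pytest.approx(pvals, abs=1e-10)
            assert fit.llf == pytest.approx(llf, abs=1e-8)

    def test_perfect_fit(self):
        x = np.arange(6.0)
        fit = fit_glm(2 * x, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.deviance == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_k_counts_variance(self):
        fit = fit_glm(np.array([1.0, 2, 3, 5]), pd.DataFrame({"x": [0.0, 1, 2, 4]}))
        assert fit.k == 3  # intercept + slope + residual variance

    def test_singular_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="singular"):
            fit_glm(np.arange(4.0), X)


class TestPoissonFit:
    def test_intercept_only_closed_form(self):
        fit = fit_glm(np.array([3, 3, 3]), None, family="poisson")
        assert fit.params["intercept"] == pytest.approx(np.log(3), abs=1e-8)

    def test_matches_direct_newton(self, rng):
        for _ in range(10):
            n = 25
            X = rng.normal(size=(n, 2)) * 0.5
            mu = np.exp(0.5 + X @ np.array([0.4, -0.3]))
            y = rng.poisson(mu)
            fit = fit_glm(y, pd.DataFrame(X, columns=["a", "b"]), family="poisson")
            ref = poisson_newton_reference(y.astype(float), X)
            assert fit.params.to_numpy() == pytest.approx(ref, abs=1e-6)

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_glm(np.array([1.5, 2.0, 3.0]), None, family="poisson")


class TestInformationCriteria:
    def test_aicc_formula(self):
        fit = GlmFit(
            family="gaussian", predictor_names=(), params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float), statistics=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float), llf=-50.0, deviance=1.0, null_deviance=2.0,
            n=12, k=3, df_resid=9, fitted=np.zeros(12), residuals=np.zeros(12),
            pearson_chi2=1.0,
        )
        assert aicc(fit) == pytest.approx(109.0)  # 106 + 24/8

    def test_aicc_converges_to_aic_for_large_n(self):
        fit_small = fit_glm(np.arange(10.0) + np.sin(np.arange(10)), None)
        rng = np.random.default_rng(0)
        y = rng.normal(size=5000)
        fit_big = fit_glm(y, None)
        aic_big = -2 * fit_big.llf + 2 * fit_big.k
        assert abs(aicc(fit_big) - aic_big) < 0.01
        aic_small = -2 * fit_small.llf + 2 * fit_small.k
        assert abs(aicc(fit_small) - aic_small) > 0.5

    def test_aicc_undefined_when_saturated(self):
        fit = fit_glm(np.array([1.0, 2, 3, 1]), pd.DataFrame({"x": [0.0, 1, 2, 3]}))
        with pytest.raises(ValueError):
            aicc(fit)  # n=4, k=3 -> n-k-1 = 0

    def test_qaicc_with_unit_dispersion_adds_only_parameter_penalty(self):
        y = np.array([2, 5, 3, 8, 4, 6, 9, 3, 2, 7, 5, 4])
        fit = fit_glm(y, None, family="poisson")
        a, qa = aicc(fit), qaicc(fit, 1.0)
        n, k = fit.n, fit.k
        extra = (2 * (k + 1) + 2 * (k + 1) * (k + 2) / (n - k - 2)) - (
            2 * k + 2 * k * (k + 1) / (n - k - 1)
        )
        assert qa - a == pytest.approx(extra, abs=1e-10)


class TestAkaikeWeights:
    def test_two_model_case(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.731, 0.269], abs=5e-4)

    def test_three_model_case(self):
        w = akaike_weights([0.0, 2.0, 4.0])
        assert w == pytest.approx([0.665, 0.245, 0.090], abs=5e-4)

    def test_invariant_to_constant_shift(self, rng):
        c = rng.uniform(50, 80, size=6)
        assert akaike_weights(c) == pytest.approx(akaike_weights(c + 123.4))

    def test_weights_sum_to_one(self, rng):
        assert akaike_weights(rng.uniform(0, 30, 10)).sum() == pytest.approx(1.0)


class TestAllSubsets:
    @pytest.fixture
    def selection(self, rng):
        n = 12
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = 2.0 + 1.5 * X["a"] + rng.normal(scale=0.5, size=n)
        return all_subsets(y, X)

    def test_enumerates_all_subsets(self, selection):
        assert len(selection.table) == 16
        assert selection.table["weight"].sum() == pytest.approx(1.0)
        assert selection.table["delta"].iloc[0] == 0.0
        assert selection.table["criterion"].is_monotonic_increasing

    def test_includes_intercept_only_model(self, selection):
        assert () in list(selection.table["predictors"])

    def test_true_predictor_ranks_first_in_importance(self, selection):
        imp = multimodel_summary(selection)
        assert imp.index[0] == "a"
        assert 0 <= imp["importance"].max() <= 1


class TestConfidenceSet:
    def _table(self, weights):
        df = pd.DataFrame(
            {
                "predictors": [(f"m{i}",) for i in range(len(weights))],
                "criterion": np.arange(len(weights), dtype=float),
                "weight": weights,
            }
        )
        df["delta"] = df["criterion"] - df["criterion"].min()
        df["cum_weight"] = df["weight"].cumsum()
        from riparia.glm import ModelSelectionTable

        return ModelSelectionTable(df, [], "AICc", "gaussian")

    def test_single_model(self):
        assert confidence_set(self._table([1.0]))["n_models"] == 1

    def test_prefix_until_mass_exceeded(self):
        assert confidence_set(self._table([0.6, 0.3, 0.08, 0.02]))["n_models"] == 3

    def test_uniform_weights_need_every_model(self):
        assert confidence_set(self._table([1 / 16] * 16))["n_models"] == 16


class TestModelAveraging:
    def test_hand_case(self):
        from riparia.glm import ModelSelectionTable

        df = pd.DataFrame(
            {
                "predictors": [("x",), ("x", "z")],
                "criterion": [10.0, 10.0],
                "weight": [0.5, 0.5],
            }
        )
        df["delta"] = 0.0
        df["cum_weight"] = df["weight"].cumsum()
        fits = []
        for beta in (1.0, 3.0):
            fits.append(
                GlmFit(
                    family="gaussian", predictor_names=("x",),
                    params=pd.Series({"intercept": 0.0, "x": beta}),
                    bse=pd.Series({"intercept": 0.0, "x": 0.0}),
                    statistics=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
                    llf=0.0, deviance=1.0, null_deviance=2.0, n=10, k=3, df_resid=7,
                    fitted=np.zeros(10), residuals=np.zeros(10), pearson_chi2=1.0,
                )
            )
        t = ModelSelectionTable(df, fits, "AICc", "gaussian")
        est = importance_and_average(t, "x")
        assert est.importance == pytest.approx(1.0)
        assert est.beta_avg == pytest.approx(2.0)
        assert est.unconditional_variance == pytest.approx(1.0)

    def test_constant_coefficient_has_zero_variance(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        y = 3.0 * X["x"].to_numpy()  # exact: every containing model agrees
        t = all_subsets(pd.Series(y), X)
        est = importance_and_average(t, "x")
        assert est.beta_avg == pytest.approx(3.0)
        assert est.unconditional_variance == pytest.approx(0.0, abs=1e-12)

    def test_absent_predictor_flagged(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        t = all_subsets(pd.Series(rng.normal(size=10)), X)
        est = importance_and_average(t, "nope")
        assert est.importance == 0.0 and np.isnan(est.beta_avg)


class TestExplainedDeviance:
    def test_intercept_only_is_zero(self, rng):
        y = rng.normal(size=10)
        assert explained_deviance(fit_glm(y, None)) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_fit_is_100(self):
        x = np.arange(8.0)
        fit = fit_glm(3 * x + 1, pd.DataFrame({"x": x}))
        assert explained_deviance(fit) == pytest.approx(100.0)

    def test_constant_response_undefined(self):
        with pytest.raises(ValueError):
            explained_deviance(fit_glm(np.ones(5), None))
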