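"""Conditional quasi-Poisson fit: oracle equivalence, dispersion, qAIC, selection.

The core oracle is the unconditional Poisson GLM with explicit stratum
indicator columns (statsmodels): profiling the stratum intercepts analytically
must reproduce its coefficients and covariance sub-block exactly.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import tempmort as tm
from tempmort.conditional import FitError
from tempmort.exposure import ValidationError


def _random_instance(rng, n_max=500, s_max=40, p_max=6):
    n = int(rng.integers(40, n_max + 1))
    S = int(rng.integers(3, s_max + 1))
    p = int(rng.integers(1, p_max + 1))
    strata = rng.integers(0, S, n)
    W = rng.normal(size=(n, p))
    beta = rng.normal(0, 0.3, p)
    alpha = rng.normal(0, 0.5, S)
    y = rng.poisson(np.exp(0.3 + W @ beta + alpha[strata]))
    return y, W, strata


def _dummy_glm(y, W, strata):
    D = pd.get_dummies(pd.Series(strata).astype(str)).values.astype(float)
    X = np.hstack([W, D])
    return sm.GLM(y, X, family=sm.families.Poisson()).fit()


class TestOracleEquivalence:
    def test_matches_explicit_dummy_glm_on_random_instances(self, rng):
        p_checked = 0
        for _ in range(25):
            y, W, strata = _random_instance(rng)
            # keep only instances where every stratum is informative, so the
            # dummy GLM is directly comparable
            totals = pd.Series(y).groupby(strata).sum()
            if (totals == 0).any():
                keep = ~np.isin(strata, totals.index[totals == 0])
                y, W, strata = y[keep], W[keep], strata[keep]
            fit = tm.fit_conditional_quasipoisson(y, W, strata)
            if fit.n_strata_dropped:
                continue
            glm = _dummy_glm(y, W, strata)
            p = W.shape[1]
            assert np.abs(fit.theta - glm.params[:p]).max() < 1e-6
            phi = glm.pearson_chi2 / glm.df_resid
            V = glm.cov_params()[:p, :p] * phi
            assert np.abs(fit.vcov - V).max() / max(np.abs(V).max(), 1e-12) < 1e-5
            assert fit.dispersion == pytest.approx(phi, rel=1e-6)
            assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)
            p_checked += 1
        assert p_checked >= 20

    def test_two_day_single_stratum_closed_form(self):
        fit = tm.fit_conditional_quasipoisson(
            [2, 1], np.array([[1.0], [0.0]]), ["s", "s"]
        )
        assert fit.theta[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_column_shift_invariance(self, rng):
        # adding a constant to a design column is absorbed by stratum intercepts
        y, W, strata = _random_instance(rng, n_max=200, s_max=10, p_max=3)
        fit1 = tm.fit_conditional_quasipoisson(y, W, strata)
        W2 = W.copy()
        W2[:, 0] += 37.5
        fit2 = tm.fit_conditional_quasipoisson(y, W2, strata)
        np.testing.assert_allclose(fit1.theta, fit2.theta, atol=1e-7)
        np.testing.assert_allclose(fit1.vcov, fit2.vcov, rtol=1e-5, atol=1e-10)

    def test_uninformative_strata_do_not_move_estimates(self, rng):
        y, W, strata = _random_instance(rng, n_max=200, s_max=10, p_max=3)
        fit1 = tm.fit_conditional_quasipoisson(y, W, strata)
        # append a zero-count stratum and a constant-design stratum
        y2 = np.r_[y, [0, 0], [3, 1]]
        W2 = np.vstack([W, rng.normal(size=(2, W.shape[1])), np.ones((2, W.shape[1]))])
        strata2 = np.r_[strata, [900, 900], [901, 901]]
        fit2 = tm.fit_conditional_quasipoisson(y2, W2, strata2)
        assert fit2.n_strata_dropped == 2
        np.testing.assert_allclose(fit1.theta, fit2.theta, atol=1e-10)

    def test_vcov_symmetric_psd(self, rng):
        y, W, strata = _random_instance(rng, n_max=300, s_max=15, p_max=4)
        fit = tm.fit_conditional_quasipoisson(y, W, strata)
        np.testing.assert_allclose(fit.vcov, fit.vcov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-10)


class TestDispersion:
    def test_poisson_data_dispersion_near_one(self):
        rng = np.random.default_rng(7)
        n, S = 2000, 400
        strata = np.repeat(np.arange(S), n // S)
        W = rng.normal(size=(n, 2))
        y = rng.poisson(np.exp(0.5 + W @ [0.2, -0.1] + rng.normal(0, 0.3, S)[strata]))
        fit = tm.fit_conditional_quasipoisson(y, W, strata)
        assert 0.85 <= fit.dispersion <= 1.15

    def test_negative_binomial_data_overdispersed(self):
        rng = np.random.default_rng(8)
        n, S, size = 2000, 400, 5.0
        strata = np.repeat(np.arange(S), n // S)
        W = rng.normal(size=(n, 2))
        mu = np.exp(1.0 + W @ [0.2, -0.1] + rng.normal(0, 0.3, S)[strata])
        y = rng.negative_binomial(size, size / (size + mu))
        fit = tm.fit_conditional_quasipoisson(y, W, strata)
        assert fit.dispersion > 1.2


class TestFailureModes:
    def test_collinear_design_errors_with_nullspace_dim(self, rng):
        y, W, strata = _random_instance(rng, n_max=200, s_max=10, p_max=3)
        W = np.hstack([W, W[:, :1] * 2.0])
        with pytest.raises(FitError, match="null-space dimension 1"):
            tm.fit_conditional_quasipoisson(y, W, strata)

    def test_no_informative_strata_errors(self):
        with pytest.raises(FitError, match="no informative strata"):
            tm.fit_conditional_quasipoisson(
                [0, 0], np.array([[1.0], [0.0]]), ["s", "s"]
            )

    def test_misaligned_rows_error(self):
        with pytest.raises(ValidationError, match="misaligned"):
            tm.fit_conditional_quasipoisson([1, 2, 3], np.ones((2, 1)), ["a", "a"])


class TestQaic:
    def test_reduces_to_aic_at_unit_dispersion(self):
        fit = tm.ConditionalFit(
            theta=np.zeros(3), vcov=np.eye(3), dispersion=1.0, loglik=-100.0,
            qaic=np.nan, n_obs_used=10, n_strata_used=2, n_strata_dropped=0,
        )
        assert tm.qaic(fit, p=3) == pytest.approx(-2 * -100.0 + 2 * 3)

    def test_penalty_linear_in_p_and_dispersion(self):
        base = tm.ConditionalFit(
            theta=np.zeros(4), vcov=np.eye(4), dispersion=1.7, loglik=-55.0,
            qaic=np.nan, n_obs_used=10, n_strata_used=2, n_strata_dropped=0,
        )
        doubled = tm.ConditionalFit(
            theta=np.zeros(4), vcov=np.eye(4), dispersion=3.4, loglik=-55.0,
            qaic=np.nan, n_obs_used=10, n_strata_used=2, n_strata_dropped=0,
        )
        assert tm.qaic(doubled, 4) - tm.qaic(base, 4) == pytest.approx(2 * 4 * 1.7)
        assert tm.qaic(base, 0) == pytest.approx(-2 * -55.0)


class TestSelectSpec:
    def _builder(self, y, designs, strata):
        return lambda spec: (y, designs[spec], strata)

    def test_single_candidate_degenerate(self, rng):
        y, W, strata = _random_instance(rng, n_max=200, s_max=10, p_max=3)
        spec, fit, table = tm.select_spec(["only"], lambda s: (y, W, strata))
        assert spec == "only" and len(table) == 1 and table["selected"].all()

    def test_identical_designs_tie_break_on_order(self, rng):
        y, W, strata = _random_instance(rng, n_max=200, s_max=10, p_max=3)
        spec, _, table = tm.select_spec(["a", "b"], lambda s: (y, W, strata))
        assert spec == "a"
        assert table.loc[table["selected"], "candidate"].iloc[0] == 0

    def test_prefers_true_smaller_model_most_of_the_time(self):
        # nested candidates on data generated from the smaller model
        wins = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n, S = 1500, 300
            strata = np.repeat(np.arange(S), n // S)
            W_small = rng.normal(size=(n, 1))
            W_big = np.hstack([W_small, rng.normal(size=(n, 3))])
            y = rng.poisson(
                np.exp(0.6 + W_small[:, 0] * 0.3 + rng.normal(0, 0.2, S)[strata])
            )
            designs = {"small": W_small, "big": W_big}
            spec, _, _ = tm.select_spec(
                ["small", "big"], lambda s: (y, designs[s], strata)
            )
            wins += spec == "small"
        assert wins >= reps // 2 + 1

    def test_all_candidates_fail_aggregates(self):
        y = np.array([0, 0])
        W = np.ones((2, 1))
        with pytest.raises(FitError, match="all candidate specs failed"):
            tm.select_spec(["a", "b"], lambda s: (y, W, ["s", "s"]))
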