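"""Covariate transforms, deviation coding, OLS, stepwise AIC, Spearman/BH."""

import numpy as np
import pandas as pd
import pytest

import polyprof as pp
from polyprof.regression import expand_deviation_coefficients
from polyprof.synthetic import standardized_effect_columns


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form (X'X)^-1 X'y with an explicit intercept column."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestTransformCovariates:
    def test_standardized_column_unchanged(self):
        x = pd.Series([-1.0, 0.0, 1.0], name="orf_gc")
        table = pd.DataFrame({"orf_gc": x})
        design, _ = pp.transform_covariates(table, log_flags=())
        assert np.allclose(design["orf_gc"], x)

    def test_log_flagged_powers_of_ten_z_score_cleanly(self):
        table = pd.DataFrame({"mrna_conc": [10.0, 100.0, 1000.0]})
        design, _ = pp.transform_covariates(table)
        # log10 -> (1,2,3); centred and reduced with sample sd 1
        assert np.allclose(design["mrna_conc"], [-1, 0, 1])

    def test_constant_column_rejected_by_name(self):
        table = pd.DataFrame({"orf_gc": [50.0, 50.0, 50.0]})
        with pytest.raises(ValueError, match="orf_gc"):
            pp.transform_covariates(table, log_flags=())

    def test_nonpositive_value_under_log_flag_rejected(self):
        table = pd.DataFrame({"mrna_conc": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="positive"):
            pp.transform_covariates(table)

    def test_rd_model_drops_orf_length_and_logs_response(self):
        table = pd.DataFrame({"orf_length": [100.0, 900.0, 2000.0],
                              "orf_gc": [40.0, 50.0, 60.0]})
        design, y = pp.transform_covariates(table, response=[0.1, 1.0, 10.0],
                                            response_kind="RD")
        assert "orf_length" not in design.columns
        assert np.allclose(y, [-1, 0, 1])


class TestDeviationCoding:
    def test_two_level_factor_gives_single_pm1_column(self):
        col = pp.encode_qualitative(pd.Series(["+", "-", "+"], name="strand"))
        assert col.shape[1] == 1
        assert set(np.unique(col)) == {-1.0, 1.0}

    def test_balanced_three_level_columns_orthogonal_to_intercept(self):
        col = pp.encode_qualitative(pd.Series(["a", "b", "c"] * 4, name="f"))
        assert np.allclose(col.sum(axis=0), 0.0)

    def test_expanded_level_coefficients_sum_to_zero(self):
        levels = pd.Series(["a", "b", "c", "a", "b", "c"], name="f")
        coefs = pd.Series({"f[a]": 0.5, "f[b]": -0.2})
        expanded = expand_deviation_coefficients(levels, coefs)
        assert expanded.sum() == pytest.approx(0.0)
        assert expanded["c"] == pytest.approx(-0.3)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="single level"):
            pp.encode_qualitative(pd.Series(["x", "x"], name="f"))


class TestFitOls:
    def test_noiseless_response_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = 1.5 + 2.0 * X["a"] - 0.5 * X["c"]
        fit = pp.fit_ols(X, y)
        assert fit.params["const"] == pytest.approx(1.5)
        assert fit.params["a"] == pytest.approx(2.0)
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(80, 4)))
        y = rng.normal(size=80)
        fit = pp.fit_ols(X, pd.Series(y))
        oracle = normal_equations_ols(X.to_numpy(), y)
        assert np.allclose(fit.params.to_numpy(), oracle, rtol=1e-8)

    def test_orthonormal_design_projects_response(self):
        # columns of Q are orthonormal; beta = Q'y reduces to the projection
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 2)))
        X = pd.DataFrame(Q - Q.mean(axis=0), columns=["x1", "x2"])
        y = 2.0 * X["x1"]
        fit = pp.fit_ols(X, y)
        assert fit.params["x1"] == pytest.approx(2.0)
        assert fit.params["x2"] == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank deficient"):
            pp.fit_ols(X, pd.Series([1.0, 2, 3, 4]))


class TestStepwiseAic:
    def _design(self, n, n_noise, beta, sigma, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, n_noise + 1)),
                         columns=["signal"] + [f"noise{i}" for i in range(n_noise)])
        y = pd.Series(beta * X["signal"] + rng.normal(0, sigma, n))
        blocks = {c: [c] for c in X.columns}
        return X, y, blocks

    def test_strong_predictor_survives_selection(self):
        hits = 0
        for seed in range(20):
            X, y, blocks = self._design(800, 9, beta=0.5, sigma=1.0, seed=seed)
            _, included = pp.stepwise_aic(X, y, blocks)
            hits += "signal" in included
        assert hits >= 19

    def test_pure_noise_predictors_mostly_all_dropped(self):
        # each noise predictor survives AIC with prob P(chi2_1 > 2) ~ 0.16,
        # so with 2 candidates the intercept-only model wins ~71% of runs
        empty = 0
        for seed in range(30):
            X, y, blocks = self._design(400, 1, beta=0.0, sigma=1.0, seed=100 + seed)
            _, included = pp.stepwise_aic(X, y, blocks)
            empty += len(included) == 0
        assert empty >= 15  # intercept-only wins in the majority of runs

    def test_selected_aic_never_above_full_model(self):
        X, y, blocks = self._design(300, 5, beta=0.3, sigma=1.0, seed=7)
        full = pp.fit_ols(X, y)
        fit, _ = pp.stepwise_aic(X, y, blocks)
        assert fit.aic <= full.aic + 1e-9

    def test_qualitative_blocks_move_together(self):
        cov, truth = pp.simulate_covariate_study(n_genes=400, seed=11)
        model = pp.TranslationRegressionModel(cov, truth.table["ro_true"])
        res = model.fit(select="aic")
        for pred in res.included_predictors:
            for col in res.blocks[pred]:
                assert col in res.params.index


class TestSpearmanBH:
    def test_monotone_relations_give_plus_minus_one(self):
        x = pd.Series(np.arange(10.0))
        covs = pd.DataFrame({"up": x**3, "down": -x})
        out = pp.spearman_bh(x, covs)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_bh_step_up_arithmetic(self):
        # raw p (0.01, 0.02, 0.03, 0.04) with m=4 all adjust to 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_constant_column_reported_missing(self):
        x = pd.Series(np.arange(8.0))
        covs = pd.DataFrame({"flat": np.ones(8), "ok": x})
        out = pp.spearman_bh(x, covs)
        assert np.isnan(out.loc["flat", "rho"])
        assert not np.isnan(out.loc["ok", "p_adjusted"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            pp.spearman_bh(pd.Series([1.0, 2.0]), pd.DataFrame({"x": [1.0, 2.0]}))


class TestModelRecovery:
    def test_true_signs_recovered_in_full_model(self):
        cov, truth = pp.simulate_covariate_study(n_genes=800, seed=21)
        res = pp.TranslationRegressionModel(cov, truth.table["ro_true"]).fit()
        assert 0.1 < res.r_squared < 0.45
        eff = standardized_effect_columns(cov)
        fit = pp.fit_ols(eff[list(truth.beta_true)], truth.table["ro_true"])
        for pred, beta in truth.beta_true.items():
            assert np.sign(fit.params[pred]) == np.sign(beta)

    def test_deviation_coefficients_sum_to_zero_in_fit(self):
        cov, truth = pp.simulate_covariate_study(n_genes=500, seed=22)
        res = pp.TranslationRegressionModel(cov, truth.table["ro_true"]).fit()
        for pred, expanded in res.level_coefficients.items():
            assert expanded.sum() == pytest.approx(0.0, abs=1e-10)
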