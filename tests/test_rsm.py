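"""Quadratic response-surface fitting, ANOVA and standardized effects."""

import numpy as np
import pandas as pd
import pytest

import extractopt as xo
from extractopt import rsm
from extractopt.rsm import SingularDesignError, UnderdeterminedError

from conftest import normal_equations_ols


class TestFitQuadratic:
    def test_matches_normal_equations_oracle(self, umbu_design, umbu_responses):
        """OLS solution equals an explicit (X'X)^-1 X'y computation."""
        X = rsm.model_matrix(umbu_design.coded)
        for name in umbu_responses.columns:
            y = umbu_responses[name].to_numpy(dtype=float)
            beta_o, se_o, resid_o = normal_equations_ols(X, y)
            fit = xo.fit_quadratic(umbu_design, umbu_responses[name], name)
            np.testing.assert_allclose(fit.beta, beta_o, atol=1e-8)
            np.testing.assert_allclose(fit.se, se_o, atol=1e-8)
            np.testing.assert_allclose(fit.residuals, resid_o, atol=1e-8)

    def test_noise_free_surface_recovered_exactly(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        true = np.array([100, 5, -3, 2, -4, 1.5, 0.5, 2, -1, 0.7])
        y = rsm.model_matrix(dm.coded) @ true
        fit = xo.fit_quadratic(dm, y)
        np.testing.assert_allclose(fit.beta, true, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degrees_of_freedom(self, umbu_fits):
        for fit in umbu_fits.values():
            assert (fit.df_model, fit.df_residual) == (9, 7)
            assert fit.df_model + fit.df_residual == 17 - 1

    def test_fitted_plus_residuals_reproduce_observations(self, umbu_fits):
        for fit in umbu_fits.values():
            np.testing.assert_allclose(
                fit.fitted + fit.residuals, fit.observed, atol=1e-8
            )

    def test_run_permutation_invariance(self, umbu_design, umbu_responses):
        """Shuffling runs (with run_id alignment) leaves the fit unchanged."""
        rng = np.random.default_rng(7)
        perm = rng.permutation(umbu_responses.index.to_numpy())
        shuffled = umbu_responses.loc[perm, "TPC"]
        a = xo.fit_quadratic(umbu_design, umbu_responses["TPC"], "TPC")
        b = xo.fit_quadratic(umbu_design, shuffled, "TPC")
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)

    def test_underdetermined_raises(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        dm.points = dm.points[:10]  # 10 runs, 10 terms
        with pytest.raises(UnderdeterminedError):
            xo.fit_quadratic(dm, np.arange(10.0))

    def test_rank_deficient_raises(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        # collapse two factors onto each other -> singular quadratic
        for i, p in enumerate(dm.points):
            c = (p.coded[0], p.coded[0], p.coded[2])
            dm.points[i] = xo.DesignPoint(p.run_id, c, p.real, p.block)
        with pytest.raises(SingularDesignError):
            xo.fit_quadratic(dm, np.arange(17.0))


class TestAnova:
    def test_ss_and_df_additivity(self, umbu_fits, umbu_design):
        for name, fit in umbu_fits.items():
            tab = xo.anova(fit, umbu_design)
            assert tab.loc["model", "SS"] + tab.loc["residual", "SS"] == pytest.approx(
                tab.loc["total", "SS"], rel=1e-6
            )
            assert tab.loc["lack_of_fit", "SS"] + tab.loc[
                "pure_error", "SS"
            ] == pytest.approx(tab.loc["residual", "SS"], rel=1e-6)
            assert (
                tab.loc["model", "df"] + tab.loc["residual", "df"]
                == tab.loc["total", "df"]
            )
            assert (
                tab.loc["lack_of_fit", "df"] + tab.loc["pure_error", "df"]
                == tab.loc["residual", "df"]
            )

    def test_pure_error_from_center_replicates(self, umbu_fits, umbu_design):
        """TPC center replicates (1479, 1379, 1405) about their mean 1421:
        58^2 + 42^2 + 16^2 = 5384 on 2 df."""
        tab = xo.anova(umbu_fits["TPC"], umbu_design)
        assert tab.loc["pure_error", "SS"] == pytest.approx(5384, rel=1e-9)
        assert tab.loc["pure_error", "df"] == 2

    def test_constant_response_gives_zero_model_f(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        fit = xo.fit_quadratic(dm, np.full(17, 42.0))
        tab = xo.anova(fit, dm)
        assert tab.loc["model", "SS"] == pytest.approx(0.0, abs=1e-16)
        assert tab.loc["model", "F"] == 0.0

    def test_lack_of_fit_unavailable_without_replicates(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 1)
        rng = np.random.default_rng(0)
        fit = xo.fit_quadratic(dm, rng.normal(size=dm.n_runs))
        tab = xo.anova(fit, dm)
        assert np.isnan(tab.loc["lack_of_fit", "SS"])
        assert np.isfinite(tab.loc["model", "F"])

    def test_r_squared_equals_squared_correlation(self, umbu_fits):
        for fit in umbu_fits.values():
            corr = np.corrcoef(fit.fitted, fit.observed)[0, 1]
            assert fit.r_squared == pytest.approx(corr**2, abs=1e-9)

    def test_f_grows_as_noise_shrinks(self, three_factors):
        """Over a decreasing noise ladder, R^2 -> 1 and model F increases."""
        true = np.array([50, 8, -6, 3, -2, 1, 0.5, 1.5, -0.5, 0.2])
        f_vals, r2_vals = [], []
        for i, sigma in enumerate([8.0, 2.0, 0.5, 0.125]):
            spec = xo.SyntheticCcdSpec(
                three_factors, 3, {"y": true}, sigma=sigma, seed=11
            )
            dm, resp = xo.simulate_ccd_experiment(spec)
            fit = xo.fit_quadratic(dm, resp["y"])
            f_vals.append(xo.anova(fit, dm).loc["model", "F"])
            r2_vals.append(fit.r_squared)
        assert all(np.diff(f_vals) > 0)
        assert all(np.diff(r2_vals) > 0)
        assert r2_vals[-1] > 0.999


class TestCriticalF:
    def test_reference_quantile(self):
        assert xo.critical_f(9, 7, 0.05) == pytest.approx(3.68, abs=0.005)

    def test_median_of_symmetric_f_is_one(self):
        assert xo.critical_f(5, 5, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_chi_square_limit(self):
        assert xo.critical_f(1, 10**6, 0.05) == pytest.approx(3.841, abs=0.001)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            xo.critical_f(0, 7)
        with pytest.raises(ValueError):
            xo.critical_f(9, 7, alpha=1.5)


class TestStandardizedEffects:
    def test_matches_beta_over_se_oracle(self, umbu_design, umbu_responses):
        X = rsm.model_matrix(umbu_design.coded)
        y = umbu_responses["ABTS"].to_numpy(dtype=float)
        beta_o, se_o, _ = normal_equations_ols(X, y)
        fit = xo.fit_quadratic(umbu_design, umbu_responses["ABTS"], "ABTS")
        eff = xo.standardized_effects(fit)
        t_oracle = dict(zip(fit.terms, beta_o / se_o))
        for term, row in eff.iterrows():
            assert row["t"] == pytest.approx(t_oracle[term], abs=1e-8)

    def test_tpc_sign_pattern(self, umbu_fits):
        """For total phenolics: ethanol linear negative and dominant,
        ethanol quadratic significant, temperature and solid-liquid linear
        positive and significant."""
        eff = xo.standardized_effects(umbu_fits["TPC"])
        assert eff.index[0] == "ethanol"
        assert eff.loc["ethanol", "t"] < 0 and eff.loc["ethanol", "significant"]
        assert eff.loc["ethanol^2", "significant"]
        assert eff.loc["temperature", "t"] > 0 and eff.loc["temperature", "significant"]
        assert (
            eff.loc["solid_liquid", "t"] > 0 and eff.loc["solid_liquid", "significant"]
        )

    def test_single_true_effect_ranks_first(self, three_factors):
        beta = np.zeros(10)
        beta[2] = 10.0  # ethanol linear only
        spec = xo.SyntheticCcdSpec(
            three_factors, 3, {"y": beta}, sigma=1e-4, seed=3
        )
        dm, resp = xo.simulate_ccd_experiment(spec)
        fit = xo.fit_quadratic(dm, resp["y"])
        assert xo.standardized_effects(fit).index[0] == "ethanol"

    def test_exact_quadratic_gives_huge_effects(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        y = rsm.model_matrix(dm.coded) @ np.arange(1.0, 11.0)
        fit = xo.fit_quadratic(dm, y)
        eff = xo.standardized_effects(fit)
        assert (np.abs(eff["t"]) > 1e6).all()
        assert eff["significant"].all()

    def test_zero_residual_variance_flagged_infinite(self, umbu_fits):
        """With an exactly-zero residual standard error, effects are
        reported infinite with a warning rather than silently dropped."""
        base = umbu_fits["TPC"]
        fit = xo.QuadraticFit(**{**base.__dict__})
        fit.se = np.zeros_like(base.se)
        with pytest.warns(RuntimeWarning):
            eff = xo.standardized_effects(fit)
        assert np.isinf(np.abs(eff["t"])).all()


class TestPredictAndGrid:
    def test_prediction_identity_at_design_points(self, umbu_fits, umbu_design):
        for fit in umbu_fits.values():
            preds = xo.predict(fit, umbu_design.coded)
            np.testing.assert_allclose(
                preds + fit.residuals, fit.observed, atol=1e-8
            )

    def test_center_prediction_is_intercept(self, umbu_fits):
        fit = umbu_fits["TPC"]
        assert xo.predict(fit, np.zeros(3)) == pytest.approx(fit.beta[0])

    def test_constant_fit_grid_is_flat(self, three_factors):
        dm = xo.generate_rotatable_ccd(three_factors, 3)
        fit = xo.fit_quadratic(dm, np.full(17, 7.0) + 1e-9 * np.arange(17))
        grid = xo.response_surface_grid(fit, vary=(0, 1), resolution=5)
        np.testing.assert_allclose(grid["predicted"], 7.0, atol=1e-6)

    def test_tpc_surface_peak_location(self, umbu_fits, umbu_design):
        """With solid-liquid fixed at center, the phenolics surface peaks at
        high temperature (> 60 °C) and ethanol between 20 and 50%."""
        fit = umbu_fits["TPC"]
        grid = xo.response_surface_grid(fit, vary=(0, 1), resolution=201)
        best = grid.loc[grid["predicted"].idxmax()]
        temp = umbu_design.factors[0].to_real(best["temperature"])
        eth = umbu_design.factors[1].to_real(best["ethanol"])
        assert temp > 60.0
        assert 20.0 < eth < 50.0

    def test_grid_max_agrees_with_fine_refinement(self, umbu_fits):
        """Coarse-grid argmax is within one coarse step of a 10x finer grid."""
        fit = umbu_fits["ABTS"]
        coarse = xo.response_surface_grid(fit, vary=(0, 1), resolution=201)
        fine = xo.response_surface_grid(fit, vary=(0, 1), resolution=2001)
        cb = coarse.loc[coarse["predicted"].idxmax()]
        fb = fine.loc[fine["predicted"].idxmax()]
        a = (2.0**3) ** 0.25
        step = 2 * a / 200
        assert abs(cb["temperature"] - fb["temperature"]) <= step + 1e-12
        assert abs(cb["ethanol"] - fb["ethanol"]) <= step + 1e-12

    def test_equal_vary_indices_rejected(self, umbu_fits):
        with pytest.raises(ValueError):
            xo.response_surface_grid(umbu_fits["TPC"], vary=(1, 1))
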