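"""OLS fitting, cross-validation, Spearman correlation, diagnostics."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fit_normal_equations

from vbsalab.regression import (cross_validate, fit_by_group, fit_linear,
                                residual_diagnostics, spearman_matrix)


def planted_data(n, c1=1.9, c0=5.0, sigma=1.0, seed=0, c_stature=None):
    rng = np.random.default_rng(seed)
    vbsa = rng.uniform(40.0, 160.0, n)
    wbsa = c1 * vbsa + c0
    extra = None
    if c_stature is not None:
        stature = rng.uniform(120.0, 220.0, n)
        wbsa = wbsa + c_stature * stature
        extra = {"stature": stature}
    wbsa = wbsa + rng.normal(0.0, sigma, n)
    return vbsa, wbsa, extra


class TestFitLinear:
    def test_noiseless_recovery(self):
        vbsa = np.linspace(10, 100, 50)
        coef = fit_linear(vbsa, 2.0 * vbsa + 3.0)
        assert coef["c1"] == pytest.approx(2.0, abs=1e-9)
        assert coef["c0"] == pytest.approx(3.0, abs=1e-9)

    def test_two_points_interpolated_exactly(self):
        coef = fit_linear([1.0, 3.0], [5.0, 9.0])
        assert coef["c1"] == pytest.approx(2.0)
        assert coef["c0"] == pytest.approx(3.0)

    def test_matches_normal_equation_oracle(self):
        vbsa, wbsa, extra = planted_data(5000, sigma=1.0, seed=1,
                                         c_stature=0.3)
        coef = fit_linear(vbsa, wbsa, extra)
        X = np.stack([np.ones_like(vbsa), vbsa, extra["stature"]], axis=1)
        oracle = fit_normal_equations(X, wbsa)
        np.testing.assert_allclose(
            [coef["c0"], coef["c1"], coef["c2_stature"]], oracle, rtol=1e-8)
        # planted value recovered within 3 standard errors
        resid = wbsa - X @ oracle
        se = np.sqrt(resid.var(ddof=3) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(coef["c1"] - 1.9) < 3 * se

    def test_residual_orthogonality(self):
        vbsa, wbsa, _ = planted_data(500, sigma=2.0, seed=3)
        coef = fit_linear(vbsa, wbsa)
        resid = wbsa - (coef["c1"] * vbsa + coef["c0"])
        X = np.stack([np.ones_like(vbsa), vbsa], axis=1)
        assert np.abs(X.T @ resid).max() < 1e-8 * np.abs(wbsa).sum()

    def test_collinear_design_named(self):
        vbsa = np.linspace(10, 100, 30)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_linear(vbsa, 2 * vbsa, {"twice_vbsa": 2 * vbsa})

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestCrossValidate:
    def test_noiseless_has_zero_error(self):
        vbsa = np.linspace(10, 100, 200)
        fit = cross_validate(vbsa, 2 * vbsa + 3, k=10, seed=0)
        assert fit.cv_rmse <= 1e-9
        assert fit.cv_mape <= 1e-9

    def test_rmse_matches_noise_floor(self):
        vbsa, wbsa, _ = planted_data(5000, sigma=2.0, seed=7)
        fit = cross_validate(vbsa, wbsa, k=10, seed=0)
        assert 1.9 <= fit.cv_rmse <= 2.1
        assert fit.cv_mspe == pytest.approx(fit.cv_rmse ** 2, rel=1e-12)

    def test_seeded_determinism(self):
        vbsa, wbsa, _ = planted_data(400, sigma=1.0, seed=2)
        f1 = cross_validate(vbsa, wbsa, k=10, seed=5)
        f2 = cross_validate(vbsa, wbsa, k=10, seed=5)
        assert f1.cv_rmse == f2.cv_rmse and f1.cv_mape == f2.cv_mape

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cross_validate([1.0, 2, 3], [1.0, 2, 3], k=10)

    def test_cv_error_not_optimistic(self):
        # CV RMSE should on average exceed the in-sample residual SE
        diffs = []
        for seed in range(20):
            vbsa, wbsa, _ = planted_data(300, sigma=2.0, seed=100 + seed)
            fit = cross_validate(vbsa, wbsa, k=10, seed=seed)
            diffs.append(fit.cv_rmse - fit.residual_se * np.sqrt(298 / 300))
        assert np.mean(diffs) > 0


class TestSpearman:
    def test_monotone_pair(self):
        x = np.linspace(0, 10, 20)
        tab = pd.DataFrame({"a": x, "b": np.exp(x), "c": -x ** 3})
        cm = spearman_matrix(tab)
        assert cm.to_frame().loc["a", "b"] == pytest.approx(1.0)
        assert cm.to_frame().loc["a", "c"] == pytest.approx(-1.0)

    def test_ties_match_bruteforce_rank_formula(self):
        # brute-force oracle: Pearson correlation of average ranks
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        expect = np.corrcoef(ra, rb)[0, 1]
        cm = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        assert cm.to_frame().loc["a", "b"] == pytest.approx(expect, rel=1e-12)

    def test_constant_column_flagged_not_zeroed(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        cm = spearman_matrix(tab)
        assert cm.undefined == ["b"]
        assert np.isnan(cm.to_frame().loc["a", "b"])

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        cm = spearman_matrix(tab)
        np.testing.assert_allclose(cm.rho, cm.rho.T)
        np.testing.assert_allclose(np.diag(cm.rho), 1.0)
        assert np.nanmax(np.abs(cm.rho)) <= 1.0 + 1e-12

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1.0, 2]}))


class TestFitByGroup:
    def make_frame(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        vbsa = rng.uniform(40, 160, n)
        group = np.where(np.arange(n) < n // 2, "g1", "g2")
        c1 = np.where(group == "g1", 1.5, 2.5)
        wbsa = c1 * vbsa + 4 + rng.normal(0, 0.5, n)
        return pd.DataFrame({"vbsa_gt": vbsa, "wbsa": wbsa, "group": group})

    def test_single_group_equals_ungrouped(self):
        df = self.make_frame()
        df["group"] = "all"
        fits = fit_by_group(df, "group", k=10, seed=3)
        direct = cross_validate(df["vbsa_gt"], df["wbsa"], k=10, seed=3)
        assert len(fits) == 1
        assert fits[0].coefficients == direct.coefficients
        assert fits[0].cv_rmse == direct.cv_rmse

    def test_planted_per_group_slopes_recovered(self):
        fits = fit_by_group(self.make_frame(), "group", k=10, seed=0)
        by = {f.group: f for f in fits}
        assert by["g1"].coefficients["c1"] == pytest.approx(1.5, abs=0.05)
        assert by["g2"].coefficients["c1"] == pytest.approx(2.5, abs=0.05)

    def test_tiny_group_skipped_with_warning(self, caplog):
        df = self.make_frame(n=40)
        df.loc[df.index[:3], "group"] = "tiny"
        df.loc[df.index[3:], "group"] = "big"
        with caplog.at_level(logging.WARNING):
            fits = fit_by_group(df, "group", k=5, seed=0)
        assert {f.group for f in fits} == {"big"}
        assert any("tiny" in r.message for r in caplog.records)

    def test_missing_grouping_rejected(self):
        with pytest.raises(ValueError):
            fit_by_group(self.make_frame(), "no_such_column")


class TestResidualDiagnostics:
    def test_noiseless_residuals_vanish(self):
        vbsa = np.linspace(10, 100, 50)
        wbsa = 2 * vbsa + 3
        fit = cross_validate(vbsa, wbsa, k=5, seed=0)
        table, bp = residual_diagnostics(fit, vbsa, wbsa)
        assert np.abs(table["residual"]).max() < 1e-9
        assert bp["bp_pvalue"] == 1.0

    def test_homoscedastic_noise_rarely_flagged(self):
        flags = 0
        n_rep = 200
        for seed in range(n_rep):
            vbsa, wbsa, _ = planted_data(200, sigma=1.0, seed=seed)
            fit = cross_validate(vbsa, wbsa, k=5, seed=seed)
            _, bp = residual_diagnostics(fit, vbsa, wbsa)
            flags += bp["bp_pvalue"] < 0.01
        assert flags <= 0.05 * n_rep

    def test_variance_trend_detected(self):
        # variance growing with the response: heteroscedastic regime
        rng = np.random.default_rng(4)
        vbsa = rng.uniform(40, 160, 2000)
        wbsa_clean = 2 * vbsa + 5
        wbsa = wbsa_clean + rng.normal(0, 0.02 * wbsa_clean)
        fit = cross_validate(vbsa, wbsa, k=10, seed=0)
        _, bp = residual_diagnostics(fit, vbsa, wbsa)
        assert bp["bp_pvalue"] < 0.01

    def test_qq_quantiles_monotone_in_residual(self):
        vbsa, wbsa, _ = planted_data(100, sigma=1.0, seed=9)
        fit = cross_validate(vbsa, wbsa, k=5, seed=0)
        table, _ = residual_diagnostics(fit, vbsa, wbsa)
        order = np.argsort(table["residual"].to_numpy())
        assert np.all(np.diff(table["theoretical_quantile"].to_numpy()[order])
                      > 0)
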