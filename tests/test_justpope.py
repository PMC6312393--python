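import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from wheatgains import justpope as jp
from wheatgains.synthetic_trials import DGPConfig, homoscedastic, simulate_panel
from wheatgains.trial_data import Panel


def winter_cfg(seed=0, **overrides) -> DGPConfig:
    base = dict(
        release_schedule=[("A", 1992, "winter"), ("B", 1993, "winter"),
                          ("C", 1995, "winter"), ("D", 1999, "winter")],
        beta0=3000.0,
        beta1=163.0,
        beta2=300.0,
        alpha0=11.0,
        year_effect_sd=100.0,
        plot_effect_sd=150.0,
        n_plots=12,
        year_range=(1998, 2005),
        replicates=3,
        irrigated_fraction_by_type={"winter": 0.0},
        seed=seed,
    )
    base.update(overrides)
    return DGPConfig(**base)


@pytest.fixture(scope="module")
def medium_fit():
    spec = jp.default_specs()["winter"]
    panel = simulate_panel(winter_cfg(seed=8))
    return jp.fit_fgls(panel, spec)


class TestNormalEquationsOracle:
    def test_ols_matches_explicit_normal_equations(self, oracle_panel):
        panel = oracle_panel
        spec = jp.default_specs()["winter"]
        fit = jp.fit_ols(panel, spec)
        X = fit.design.matrix
        y = fit.design.y
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            fit.mean_ols["estimate"].to_numpy(), beta, rtol=1e-8
        )

    def test_fgls_matches_explicit_weighted_normal_equations(self, oracle_panel):
        panel = oracle_panel
        spec = jp.default_specs()["winter"]
        fit = jp.fit_fgls(panel, spec)
        X = fit.design.matrix
        y = fit.design.y
        w = fit.weights
        beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        np.testing.assert_allclose(
            fit.mean_fgls["estimate"].to_numpy(), beta, rtol=1e-8
        )


class TestMeanEquation:
    def test_noiseless_panel_recovers_coefficients_exactly(self):
        cfg = winter_cfg(seed=3, noiseless=True)
        panel = simulate_panel(cfg)
        fit = jp.fit_ols(panel, jp.default_specs()["winter"])
        assert fit.mean_ols.loc["lnrlyr", "estimate"] == pytest.approx(
            cfg.beta1, abs=1e-6
        )
        assert fit.mean_ols.loc["planting", "estimate"] == pytest.approx(
            cfg.beta2, abs=1e-6
        )
        assert fit.r2_ols == pytest.approx(1.0)

    def test_residuals_orthogonal_to_regressors(self, medium_fit):
        X = medium_fit.design.matrix
        u = medium_fit.ols_residuals
        scale = np.abs(X.T @ medium_fit.design.y).max()
        assert np.abs(X.T @ u).max() < 1e-8 * scale

    def test_weighted_fgls_residuals_orthogonal_to_regressors(self, medium_fit):
        X = medium_fit.design.matrix
        beta = medium_fit.mean_fgls["estimate"].to_numpy()
        u = medium_fit.design.y - X @ beta
        w = medium_fit.weights
        scale = np.abs(X.T @ (w * medium_fit.design.y)).max()
        assert np.abs(X.T @ (w * u)).max() < 1e-8 * scale

    def test_collinear_design_raises_naming_columns(self, tiny_panel_frame,
                                                    tiny_registry):
        frame = tiny_panel_frame.copy()
        frame["planting"] = 1  # constant, collinear with the intercept
        panel = Panel(frame, tiny_registry)
        with pytest.raises(jp.RankDeficiencyError, match="collinear"):
            jp.fit_ols(panel, jp.default_specs()["winter"])

    def test_single_vintage_panel_rejected(self, tiny_panel_frame, tiny_registry):
        frame = tiny_panel_frame[tiny_panel_frame["variety"] == "ALPHA"]
        panel = Panel(frame.reset_index(drop=True), tiny_registry)
        with pytest.raises(jp.FitError, match="release indices"):
            jp.fit_ols(panel, jp.default_specs()["winter"])

    def test_empty_filter_rejected(self, tiny_panel):
        with pytest.raises(jp.FitError, match="no observations"):
            jp.fit_ols(tiny_panel, jp.default_specs()["facultative"])


class TestVarianceEquation:
    def test_scaling_residuals_shifts_only_the_intercept(self, medium_fit):
        design = medium_fit.design
        spec = medium_fit.spec
        u = medium_fit.ols_residuals
        c = 3.7
        t1, _, _ = jp.fit_variance(u, design, spec)
        t2, _, _ = jp.fit_variance(c * u, design, spec)
        assert t2.loc["const", "estimate"] - t1.loc["const", "estimate"] == (
            pytest.approx(2 * np.log(c), abs=1e-8)
        )
        slopes = [t for t in t1.index if t != "const"]
        np.testing.assert_allclose(
            t2.loc[slopes, "estimate"], t1.loc[slopes, "estimate"], atol=1e-8
        )

    def test_all_zero_residuals_degenerate(self, medium_fit):
        with pytest.raises(jp.DegenerateVarianceError):
            jp.fit_variance(
                np.zeros(medium_fit.n_obs), medium_fit.design, medium_fit.spec
            )

    def test_near_zero_residuals_are_floored_and_counted(self, medium_fit):
        u = medium_fit.ols_residuals.copy()
        u[:5] = 1e-30
        _, fitted, n_floored = jp.fit_variance(u, medium_fit.design,
                                               medium_fit.spec)
        assert n_floored >= 5
        assert np.all(np.isfinite(fitted))

    def test_fgls_survives_near_interpolating_fit_via_flooring(self):
        # noiseless DGP leaves only ~1e-12 numerical residuals; the floor
        # keeps the log-variance stage finite and FGLS still recovers beta
        cfg = winter_cfg(seed=3, noiseless=True)
        fit = jp.fit_fgls(simulate_panel(cfg), jp.default_specs()["winter"])
        assert np.all(np.isfinite(fit.weights))
        assert fit.mean_fgls.loc["lnrlyr", "estimate"] == pytest.approx(
            cfg.beta1, abs=1e-6
        )


class TestFGLS:
    def test_equal_weights_limit_matches_ols(self):
        """Under a homoscedastic DGP, reweighting is pure noise and FGLS
        coefficients agree with OLS well inside one standard error."""
        spec = jp.ModelSpec("winter_nofe", wheat_type="winter",
                            fe_year=False, fe_plot=False)
        diffs, ses = [], []
        for s in range(100):
            cfg = homoscedastic(
                winter_cfg(seed=5000 + s, replicates=10,
                           year_effect_sd=0.0, plot_effect_sd=0.0)
            )
            fit = jp.fit_fgls(simulate_panel(cfg), spec)
            diffs.append(
                abs(
                    fit.mean_fgls.loc["lnrlyr", "estimate"]
                    - fit.mean_ols.loc["lnrlyr", "estimate"]
                )
            )
            ses.append(fit.mean_ols.loc["lnrlyr", "se"])
        assert np.mean(diffs) < 0.05 * np.mean(ses)

    def test_weights_positive_finite_and_normalized(self, medium_fit):
        w = medium_fit.weights
        assert np.all(np.isfinite(w)) and np.all(w > 0)
        assert w.mean() == pytest.approx(1.0)
        assert medium_fit.weight_summary["ratio"] >= 1.0

    def test_report_has_published_layout(self, medium_fit):
        report = jp.fit_report({"winter": medium_fit})
        assert list(report.columns) == [
            "wheat_type", "ols_yield", "ols_stars", "jp_variance",
            "jp_variance_stars", "jp_yield", "jp_yield_stars", "n_obs",
            "mean_yield_kg_ha",
        ]
        assert report.loc[0, "n_obs"] == medium_fit.n_obs
        full = jp.full_coefficients({"winter": medium_fit})
        assert set(full["equation"]) == {"ols_yield", "jp_variance", "jp_yield"}


class TestClusteredSE:
    def _xyu(self, seed, n=400, G=40, rho=0.0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        codes = np.repeat(np.arange(G), n // G)
        shock = rng.normal(size=G)[codes] * rho
        u = rng.normal(size=n) + shock
        beta = np.linalg.solve(X.T @ X, X.T @ u)
        return X, u - X @ beta, codes

    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(1)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, 1.5] + rng.normal(size=n) * (1 + 0.5 * np.abs(X[:, 1]))
        res = sm.OLS(y, X).fit()
        ours = jp.clustered_se(X, res.resid, np.arange(n))
        np.testing.assert_allclose(ours, res.HC1_se, rtol=1e-8)

    def test_matches_statsmodels_cluster_covariance(self):
        X, u, codes = self._xyu(2)
        y = X @ [1.0, 2.0] + u
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": codes})
        fit = sm.OLS(y, X).fit()
        ours = jp.clustered_se(X, fit.resid, codes)
        np.testing.assert_allclose(ours, res.bse, rtol=1e-8)

    def test_independent_errors_close_to_classical(self):
        ratios = []
        for s in range(100):
            X, u, codes = self._xyu(100 + s, rho=0.0)
            n, k = X.shape
            classical = np.sqrt(
                u @ u / (n - k) * np.diag(np.linalg.inv(X.T @ X))
            )
            ratios.append(jp.clustered_se(X, u, codes) / classical)
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_within_cluster_correlation_inflates_se(self):
        X, u, codes = self._xyu(7, n=2000, G=20, rho=3.0)
        n, k = X.shape
        classical = np.sqrt(u @ u / (n - k) * np.diag(np.linalg.inv(X.T @ X)))
        clustered = jp.clustered_se(X, u, codes)
        assert clustered[0] > classical[0]

    def test_single_cluster_rejected(self):
        X, u, _ = self._xyu(3)
        with pytest.raises(jp.ClusterError):
            jp.clustered_se(X, u, np.zeros(len(u), dtype=int))

    def test_twoway_scheme_runs_and_differs_from_oneway(self, medium_fit):
        design = medium_fit.design
        V1, _ = jp._robust_cov(design, medium_fit.ols_residuals, "year_region")
        V2, _ = jp._robust_cov(design, medium_fit.ols_residuals, "twoway")
        assert V1.shape == V2.shape
        assert not np.allclose(np.diag(V1), np.diag(V2))
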