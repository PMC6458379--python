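"""Design decorrelation, prediction bands, and the decision procedure."""

import numpy as np
import pytest

import trendgls as tg
from trendgls.correlation import CorrelationModel
from conftest import ar1_dataset


class TestDecorrelation:
    def test_orthogonal_columns_unchanged(self):
        # symmetric times with the quadratic column pre-centered: all
        # columns mutually orthogonal, so residualization is a no-op
        t = np.arange(-10.0, 11.0)
        X = np.column_stack([np.ones_like(t), t, t ** 2 - np.mean(t ** 2)])
        d = tg.DesignMatrix(X=X, k=2, centered=True)
        dec = tg.decorrelate_design(d)
        np.testing.assert_allclose(dec.X, d.X, atol=1e-10)

    def test_cubic_columns_become_orthogonal(self):
        d = tg.build_polynomial_design(np.arange(30.0), 3)
        dec = tg.decorrelate_design(d)
        Z = dec.X[:, 1:]
        G = Z.T @ Z
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-9 * np.max(np.diag(G))

    def test_fitted_values_invariant(self, rng):
        d = tg.build_polynomial_design(np.arange(40.0), 3)
        y = rng.normal(size=40)
        cm = CorrelationModel.ar1(0.5, 40)
        yhat1 = tg.fit_gls(d, y, cm).fittedvalues
        yhat2 = tg.fit_gls(tg.decorrelate_design(d), y, cm).fittedvalues
        np.testing.assert_allclose(yhat1, yhat2, atol=1e-9)

    def test_row_mapping_consistent(self):
        t = np.arange(1990.0, 2010.0)
        dec = tg.decorrelate_design(tg.build_polynomial_design(t, 2))
        np.testing.assert_allclose(dec.row_for(t), dec.X, atol=1e-9)


class TestPredictionInterval:
    def test_sp_tends_to_s_at_design_mean(self):
        design, y = ar1_dataset(2000, 0.0, seed=12)
        cm = CorrelationModel.identity(2000)
        t_mean = design.meta["t_mean"]
        band = tg.prediction_interval(y, design, cm, [t_mean])
        fit = tg.fit_ols(design, y)
        assert band.s_p[0] == pytest.approx(fit.s, rel=0.01)

    def test_band_width_monotone_away_from_mean(self):
        design, y = ar1_dataset(100, 0.4, seed=13)
        cm = CorrelationModel.ar1(0.4, 100)
        grid = design.meta["t_mean"] + np.array([0.0, 10.0, 30.0, 60.0, 120.0])
        band = tg.prediction_interval(y, design, cm, grid)
        widths = band.upper - band.lower
        assert np.all(np.diff(widths) >= -1e-12)

    def test_rejects_nonfinite(self):
        design, y = ar1_dataset(50, 0.0, seed=14)
        with pytest.raises(ValueError, match="non-finite"):
            tg.prediction_interval(y, design, CorrelationModel.identity(50),
                                   [np.nan])

    def test_coverage_with_known_rho(self):
        # a held-out future point falls inside the 95% band ~95% of trials
        N, rho, gap, trials = 150, 0.5, 12, 1500
        t = np.arange(N + gap, dtype=float)
        inside = 0
        rng = np.random.default_rng(15)
        cm = CorrelationModel.ar1(rho, N)
        for _ in range(trials):
            full = tg.gen_ar1(N + gap, rho, rng)
            design = tg.build_polynomial_design(t[:N], 1)
            band = tg.prediction_interval(full[:N], design, cm, [t[N + gap - 1]])
            inside += band.lower[0] <= full[-1] <= band.upper[0]
        assert inside / trials == pytest.approx(0.95, abs=0.02)

    def test_extrapolated_bands_at_least_as_wide_on_average(self):
        # widened SEs reflect the extra uncertainty of estimating rho
        N, rho, trials = 100, 0.75, 400
        rng = np.random.default_rng(160)
        design = tg.build_polynomial_design(np.arange(N, dtype=float), 1)
        E_d, V_d = tg.dw_moments(design)
        x0 = [float(N + 10)]
        ratios = []
        for _ in range(trials):
            y = tg.gen_ar1(N, rho, rng)
            e = tg.fit_ols(design, y).resid
            d, _, _ = tg.dw_statistic(e)
            r_dw = tg.rho_dw(d).rho_hat
            r_ta = tg.rho_tadw(d, E_d, V_d, N, 1).rho_hat
            if r_dw <= 0 or r_ta <= 0:
                continue
            known = tg.prediction_interval(y, design, CorrelationModel.ar1(rho, N), x0)
            ext = tg.prediction_interval(y, design, CorrelationModel.ar1(r_ta, N),
                                         x0, se_mode="extrapolated",
                                         model_dw=CorrelationModel.ar1(r_dw, N))
            ratios.append((ext.upper[0] - ext.lower[0])
                          / (known.upper[0] - known.lower[0]))
        assert np.mean(ratios) >= 1.0


class TestAutoAnalyze:
    def test_white_noise_keeps_ols(self):
        design, y = ar1_dataset(80, 0.0, seed=17)
        m = tg.TrendModel.from_series(np.arange(80.0), y, degree=1)
        report = m.fit_auto()
        assert report.branch == "ols"
        assert report.final_fit.method == "ols"
        if report.ols_dw.passed:
            assert "adequate" in " ".join(report.notes)

    def test_correlated_series_goes_gls(self):
        design, y = ar1_dataset(100, 0.6, seed=18)
        m = tg.TrendModel.from_series(np.arange(100.0), y, degree=1)
        report = m.fit_auto()
        assert report.branch in ("gls_dw", "gls_tadw", "extrapolated")
        assert report.candidates  # both candidates were evaluated
        text = report.summary()
        assert "GLS candidate" in text and "naive OLS t" in text

    def test_null_pipeline_rarely_finds_trend(self):
        # trendless AR1(0.6): the corrected slope test should not reject
        # much more often than its nominal 5% level
        from scipy import stats
        trials, N = 300, 100
        rng = np.random.default_rng(19)
        not_significant = 0
        gls_branch = 0
        for j in range(trials):
            y = tg.gen_ar1(N, 0.6, rng)
            m = tg.TrendModel.from_series(np.arange(float(N)), y, degree=1)
            report = m.fit_auto()
            if report.branch in ("gls_dw", "gls_tadw", "extrapolated"):
                gls_branch += 1
            if report.branch == "extrapolated":
                tslope = report.extrapolation.t_extrap[1]
            else:
                tslope = report.final_fit.tvalues[1]
            crit = stats.t.ppf(0.975, report.final_fit.df_resid)
            not_significant += abs(tslope) <= crit
        assert gls_branch / trials > 0.5
        assert not_significant / trials >= 0.93

    def test_spatial_data_routes_through_path(self):
        rng = np.random.default_rng(20)
        coords = rng.uniform(-100, 100, size=(80, 2))
        y = tg.gen_spatial_field(coords, 40.0, rng)
        design = tg.build_covariate_design(coords[:, :1], names=["x1"])
        report = tg.auto_analyze(tg.TrendModel(tg.Dataset(coords=coords, y=y),
                                               design))
        assert report.path is not None
        if report.branch.startswith("gls") or report.branch == "extrapolated":
            assert report.candidates[report.chosen]["r0"] > 0

    def test_model_revision_branch_on_structured_signal(self):
        # a deterministic sawtooth defeats the AR(1)/exponential error
        # model: every candidate fails and revision is recommended
        t = np.arange(120.0)
        y = ((t // 20) % 2).astype(float) * 4.0 + 0.01 * t
        m = tg.TrendModel.from_series(t, y, degree=1)
        report = m.fit_auto()
        assert report.branch in ("model_revision", "gls_dw", "gls_tadw")
        if report.branch == "model_revision":
            assert report.semivariogram is not None
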