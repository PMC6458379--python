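"""The four rho estimators, extrapolated inference and the shortcuts."""

import numpy as np
import pytest

import trendgls as tg
from trendgls.correlation import CorrelationModel
from trendgls.rho import tadw_scale
from conftest import ar1_dataset


class TestACF:
    def test_hand_values(self):
        assert tg.rho_acf([1.0, 0.0, -1.0, 0.0]).rho_hat == 0.0
        assert tg.rho_acf([1.0, 1.0, -1.0, -1.0]).rho_hat == pytest.approx(0.25)

    def test_consistency(self):
        e = tg.gen_ar1(100000, 0.8, np.random.default_rng(1))
        assert tg.rho_acf(e).rho_hat == pytest.approx(0.8, abs=0.01)


class TestDW:
    def test_values_and_clamp(self):
        assert tg.rho_dw(2.0).rho_hat == 0.0
        assert tg.rho_dw(0.850).rho_hat == pytest.approx(0.575)
        with pytest.warns(UserWarning, match="clamped"):
            est = tg.rho_dw(0.0)
        assert est.rho_hat == pytest.approx(0.9999)
        with pytest.raises(ValueError):
            tg.rho_dw(4.5)


class TestML:
    def test_null_consistency(self):
        design, y = ar1_dataset(100000, 0.0, seed=2)
        assert tg.rho_ml_iterated(design, y).rho_hat == pytest.approx(0.0, abs=0.01)

    def test_fixed_point_property(self):
        # at convergence rho equals the conditional-ML value of its own
        # GLS residuals: verify against a grid scan of the map's crossing
        design, y = ar1_dataset(30, 0.5, seed=3)
        est = tg.rho_ml_iterated(design, y)
        assert est.converged

        def step(rho):
            e = tg.fit_gls(design, y, CorrelationModel.ar1(rho, 30)).resid
            e1, e2 = e[:-1], e[1:]
            return float(((e2 - e2.mean()) * (e1 - e1.mean())).sum()
                         / ((e1 - e1.mean()) ** 2).sum())

        assert step(est.rho_hat) == pytest.approx(est.rho_hat, abs=1e-3)
        grid = np.linspace(-0.95, 0.95, 381)
        resid_map = np.array([step(r) - r for r in grid])
        crossings = grid[:-1][np.diff(np.sign(resid_map)) < 0]
        assert np.min(np.abs(crossings - est.rho_hat)) < 5e-3

    def test_close_to_conditional_likelihood_grid(self):
        # grid search maximizing the conditional Gaussian likelihood
        # (beta profiled on the N-1 transformed observations)
        design, y = ar1_dataset(30, 0.5, seed=4)
        est = tg.rho_ml_iterated(design, y)

        def neg_loglik(rho):
            Xs = design.X[1:] - rho * design.X[:-1]
            ys = y[1:] - rho * y[:-1]
            b = np.linalg.lstsq(Xs, ys, rcond=None)[0]
            return len(ys) * np.log(float(((ys - Xs @ b) ** 2).sum()))

        grid = np.linspace(-0.98, 0.98, 981)
        best = grid[int(np.argmin([neg_loglik(r) for r in grid]))]
        assert est.rho_hat == pytest.approx(best, abs=0.05)


class TestTADW:
    def test_zero_at_null_expectation(self, linear_design_40):
        E_d, V_d = tg.dw_moments(linear_design_40)
        assert tg.rho_tadw(E_d, E_d, V_d, 40, 1).rho_hat == 0.0

    def test_asymptotically_one_minus_half_d(self):
        design = tg.build_polynomial_design(np.arange(100000, dtype=float), 1)
        E_d, V_d = tg.dw_moments(design)
        for d in (0.5, 1.0, 1.8, 2.6, 3.5):
            est = tg.rho_tadw(d, E_d, V_d, 100000, 1)
            assert abs(est.rho_hat - (1.0 - d / 2.0)) < 0.01

    def test_boundary_warns(self, linear_design_40):
        E_d, V_d = tg.dw_moments(linear_design_40)
        with pytest.warns(UserWarning, match="boundary"):
            est = tg.rho_tadw(0.0, E_d, V_d, 40, 1)
        assert est.clamped and est.rho_hat < 1

    def test_scale_needs_enough_dof(self):
        with pytest.raises(ValueError, match="N - k - 4"):
            tadw_scale(5, 1)

    def test_less_biased_than_ml_at_high_rho(self):
        # mean TADW estimate at rho = 0.9, N = 100 beats iterated ML
        N, rho, trials = 100, 0.9, 400
        design = tg.build_polynomial_design(np.arange(N, dtype=float), 1)
        E_d, V_d = tg.dw_moments(design)
        rng = np.random.default_rng(41)
        tadw, ml = [], []
        for _ in range(trials):
            y = tg.gen_ar1(N, rho, rng)
            e = tg.fit_ols(design, y).resid
            d, _, _ = tg.dw_statistic(e)
            tadw.append(tg.rho_tadw(d, E_d, V_d, N, 1).rho_hat)
            ml.append(tg.rho_ml_iterated(design, y).rho_hat)
        assert abs(np.mean(tadw) - rho) < abs(np.mean(ml) - rho)

    def test_converges_to_dw_estimate(self):
        design, y = ar1_dataset(100000, 0.7, seed=6)
        e = tg.fit_ols(design, y).resid
        d, _, _ = tg.dw_statistic(e)
        E_d, V_d = tg.dw_moments(design)
        diff = abs(tg.rho_tadw(d, E_d, V_d, 100000, 1).rho_hat
                   - tg.rho_dw(d).rho_hat)
        assert diff < 0.005


class TestShortcuts:
    def test_rho_max(self):
        assert tg.rho_max(100) == pytest.approx(0.8)
        assert tg.rho_max(200) > tg.rho_max(100)
        assert tg.rho_max(40) == pytest.approx(0.8 * 0.4 ** 0.07)

    def test_effective_n(self):
        assert tg.effective_n(50, 0.0) == 50
        assert tg.effective_n(38, 0.9) == pytest.approx(2.0)
        assert tg.effective_n(100, -0.5) == pytest.approx(300.0)

    def test_scaled_se_factor(self):
        assert tg.scaled_se(1.0, 0.0) == 1.0
        assert tg.scaled_se(2.0, 0.9) == pytest.approx(2.0 * np.sqrt(19.0))

    def test_scaled_se_approximates_known_rho_gls(self):
        # large-N agreement between the SE shortcut and full GLS
        N, rho, trials = 500, 0.7, 60
        design = tg.build_polynomial_design(np.arange(N, dtype=float), 1)
        cm = CorrelationModel.ar1(rho, N)
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(trials):
            y = tg.gen_ar1(N, rho, rng)
            se_gls = tg.fit_gls(design, y, cm).bse[1]
            se_short = tg.scaled_se(tg.fit_ols(design, y).bse[1], rho)
            ratios.append(se_short / se_gls)
        assert abs(np.mean(ratios) - 1.0) < 0.15


class TestExtrapolate:
    def _pair(self, N=60, rho=0.5, seed=9):
        design, y = ar1_dataset(N, rho, seed=seed)
        e = tg.fit_ols(design, y).resid
        d, _, _ = tg.dw_statistic(e)
        E_d, V_d = tg.dw_moments(design)
        r_dw = tg.rho_dw(d).rho_hat
        r_ta = tg.rho_tadw(d, E_d, V_d, N, 1).rho_hat
        f_dw = tg.fit_gls(design, y, CorrelationModel.ar1(r_dw, N))
        f_ta = tg.fit_gls(design, y, CorrelationModel.ar1(r_ta, N))
        return f_dw, f_ta

    def test_linear_combination(self):
        f_dw, f_ta = self._pair()
        ex = tg.extrapolate(f_dw, f_ta)
        np.testing.assert_allclose(ex.t_extrap, 2 * f_ta.tvalues - f_dw.tvalues)
        assert np.all(ex.se_extrap > 0)

    def test_degenerate_extrapolation(self):
        f_dw, _ = self._pair()
        ex = tg.extrapolate(f_dw, f_dw)
        np.testing.assert_allclose(ex.t_extrap, f_dw.tvalues)

    def test_mismatched_designs_rejected(self):
        f_dw, _ = self._pair(N=60)
        g_dw, _ = self._pair(N=50)
        with pytest.raises(ValueError, match="different"):
            tg.extrapolate(f_dw, g_dw)

    def test_rho_above_bound_flagged(self):
        f_dw, f_ta = self._pair()
        ex = tg.extrapolate(f_dw, f_ta, rho_tadw_value=0.95)
        assert not ex.admissible


def test_all_estimators_near_zero_on_white_noise():
    design, y = ar1_dataset(100000, 0.0, seed=10)
    e = tg.fit_ols(design, y).resid
    d, _, _ = tg.dw_statistic(e)
    E_d, V_d = tg.dw_moments(design)
    values = [tg.rho_acf(e).rho_hat, tg.rho_dw(d).rho_hat,
              tg.rho_tadw(d, E_d, V_d, 100000, 1).rho_hat,
              tg.rho_ml_iterated(design, y).rho_hat]
    assert np.max(np.abs(values)) < 0.02
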