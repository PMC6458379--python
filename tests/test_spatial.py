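"""Nearest-new-neighbour path, spatial DW, r0 estimation, semivariogram."""

import numpy as np
import pytest

import trendgls as tg
from trendgls.spatial import NoPositiveSpatialCorrelation, reduced_design
from conftest import ar1_dataset


def brute_force_path(coords):
    """Independent greedy re-walk used as the path oracle."""
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    n = len(coords)
    order = [int(np.argmax(D.sum(1)))]
    left = set(range(n)) - {order[0]}
    while left:
        cand = sorted(left)
        dists = [D[order[-1], j] for j in cand]
        nxt = cand[int(np.argmin(dists))]
        order.append(nxt)
        left.remove(nxt)
    return order


class TestNNNPath:
    def test_1d_grid_walks_end_to_end(self):
        p = tg.nnn_path(np.arange(10, dtype=float))
        assert list(p.order) in ([*range(10)], [*range(9, -1, -1)])
        assert p.r_bar == 1.0
        # ties at both ends: lowest index wins the start
        assert p.start_index == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            coords = rng.uniform(0, 10, size=(10, 2))
            p = tg.nnn_path(coords)
            assert list(p.order) == brute_force_path(coords)

    def test_duplicate_pair_merged(self):
        coords = np.array([[0.0], [5.0], [5.0], [9.0]])
        p = tg.nnn_path(coords)
        assert p.m_coloc == 1
        assert p.n_nodes == 3
        merged_row = p.R[[np.any(r == 0.5) for r in p.R].index(True)]
        np.testing.assert_allclose(sorted(merged_row), [0.0, 0.0, 0.5, 0.5])
        # rows sum to one and reduction conserves group means
        np.testing.assert_allclose(p.R.sum(axis=1), 1.0)
        e = np.array([1.0, 2.0, 4.0, 8.0])
        assert 3.0 in p.reduce(e)  # mean of the co-located pair

    def test_all_colocated_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tg.nnn_path(np.zeros((4, 2)))


class TestSpatialDW:
    def test_equals_time_series_d_on_grid(self, rng):
        e = rng.normal(size=25)
        p = tg.nnn_path(np.arange(25, dtype=float))
        d_spatial, _, _ = tg.spatial_dw(e, p)
        # d is invariant to walking the line from either end
        assert d_spatial == pytest.approx(tg.dw_statistic(e)[0], abs=1e-12)

    def test_alternating_path_residuals(self):
        p = tg.nnn_path(np.arange(4, dtype=float))
        e = np.array([1.0, -1.0, 1.0, -1.0])
        assert tg.spatial_dw(e, p)[0] == 3.0

    def test_constant_residuals(self):
        p = tg.nnn_path(np.arange(5, dtype=float))
        assert tg.spatial_dw(np.ones(5), p)[0] == 0.0


class TestEstimateR0:
    def test_inversion_identity(self):
        # rho = e^-1 with unit mean spacing gives r0 = 1 by construction
        assert -1.0 / np.log(np.exp(-1.0)) == pytest.approx(1.0)

    def test_temporal_equivalence(self):
        # on an equally spaced grid the spatial stack reproduces the
        # time-series estimate: r0 = -1/ln(rho_hat) with rbar = 1
        design, y = ar1_dataset(80, 0.6, seed=21)
        e = tg.fit_ols(design, y).resid
        d, _, _ = tg.dw_statistic(e)
        E_d, V_d = tg.dw_moments(design)
        rho_t = tg.rho_tadw(d, E_d, V_d, 80, 1).rho_hat
        p = tg.nnn_path(np.arange(80, dtype=float))
        r0, est = tg.estimate_r0(e, p, design, method="tadw")
        assert est.rho_hat == pytest.approx(rho_t, abs=1e-12)
        assert r0 == pytest.approx(-1.0 / np.log(rho_t), abs=1e-10)

    def test_no_positive_correlation_signal(self):
        coords = np.arange(40, dtype=float)
        design = tg.build_polynomial_design(coords, 1)
        e = np.tile([1.0, -1.0], 20)  # strongly negative lag correlation
        p = tg.nnn_path(coords)
        with pytest.raises(NoPositiveSpatialCorrelation):
            tg.estimate_r0(e, p, design, method="dw")

    def test_recovery_on_random_locations(self):
        # 1-D random locations in [-100, 100], true r0 = 6
        rng = np.random.default_rng(31)
        estimates = []
        for _ in range(25):
            coords = rng.uniform(-100, 100, size=(300, 1))
            y = tg.gen_spatial_field(coords, 6.0, rng)
            design = tg.build_polynomial_design(coords[:, 0], 1)
            e = tg.fit_ols(design, y).resid
            p = tg.nnn_path(coords)
            try:
                r0, _ = tg.estimate_r0(e, p, design, method="tadw")
            except NoPositiveSpatialCorrelation:
                continue
            estimates.append(r0)
        med = np.median(estimates)
        assert 4.0 < med < 9.0


class TestSemivariogram:
    def test_hand_computed_class_means(self):
        # adjacent pairs differ by 1 (gamma = 0.5); farther pairs are equal
        e = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        coords = np.array([0.0, 0.9, 2.0, 3.1, 4.0])
        sv = tg.semivariogram_fit(e, coords=coords, n_classes=2, sill=0.5)
        # class 0: the two adjacent 0.9-pairs, gamma = 0.5 each
        assert sv.gamma_means[0] == pytest.approx(0.5)
        # class 1: two 1.1-pairs (gamma 0.5) and two 2.0-pairs (gamma 0)
        assert sv.gamma_means[1] == pytest.approx(0.25)

    def test_flat_field_flagged(self):
        # every class mean at or above the sill: no rising limb to fit
        e = np.arange(10, dtype=float)
        with pytest.warns(UserWarning, match="flat"):
            sv = tg.semivariogram_fit(e, coords=np.arange(10, dtype=float),
                                      sill=0.01)
        assert not sv.converged and sv.r0_hat is None

    def test_ar1_class_means_track_model(self):
        # long unit-spaced AR1(0.7): class means ~ sigma^2 (1 - 0.7^m)
        N, rho = 3001, 0.7
        e = tg.gen_ar1(N, rho, np.random.default_rng(50))
        sv = tg.semivariogram_fit(e, coords=np.arange(N, dtype=float),
                                  n_classes=(N - 1) // 2,
                                  sill=1.0 / (1.0 - rho ** 2))
        sig2 = 1.0 / (1.0 - rho ** 2)
        for m in range(1, 6):
            expect = sig2 * (1.0 - rho ** m)
            assert sv.gamma_means[m] == pytest.approx(expect, rel=0.10)
        # fitted correlation length near -1/ln(rho)
        assert sv.r0_hat == pytest.approx(-1.0 / np.log(rho), rel=0.5)


class TestColocatedKd:
    def test_identical_pairs_give_zero(self):
        e = np.array([1.0, 1.0, -2.0, -2.0])
        assert tg.colocated_kd(e, [[0, 1], [2, 3]], sigma2_e=1.0) == 0.0

    def test_ln2_case(self):
        # sum of squared pair differences equal to m sigma^2 gives ln 2
        e = np.array([0.0, 1.0])
        assert tg.colocated_kd(e, [[0, 1]], sigma2_e=1.0) == pytest.approx(np.log(2.0))

    def test_clamp_on_uncorrelated_pairs(self):
        e = np.array([0.0, 10.0])
        with pytest.warns(UserWarning, match="clamped"):
            kd = tg.colocated_kd(e, [[0, 1]], sigma2_e=1.0)
        assert np.isfinite(kd) and kd > 5


def test_reduced_design_preserves_contract():
    design = tg.build_polynomial_design(np.arange(6, dtype=float), 1)
    coords = np.array([[0.0], [1.0], [1.0], [2.0], [3.0], [4.0]])
    p = tg.nnn_path(coords)
    rd = reduced_design(design, p)
    assert rd.X.shape == (5, 2)
    np.testing.assert_allclose(rd.X[:, 0], 1.0)
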