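"""Model fitting: weighted objective, two-stage search, bounds, delay handling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tapsync.datatypes import AsynchronySeries
from tapsync.estimators import (
    DelayCoupledRegressor,
    FitBounds,
    LinearDriftRegressor,
    detect_boundary_hits,
    fit_model,
    median_tau,
    position_weights,
    refit_fixed_tau,
    weighted_sse,
)
from tapsync.simulate import OscParams, simulate_delay_coupled

FAST = dict(n_restarts=3, population=16, generations=30)


class TestWeightedSSE:
    def test_identical_series_zero(self):
        y = np.arange(8.0)
        assert weighted_sse(y, y) == 0.0

    def test_unit_residuals_sum_to_twelve(self):
        # weights (4,1,1,1,1,1,1,2): 4 + 6 + 2
        assert weighted_sse(np.ones(8), np.zeros(8)) == pytest.approx(12.0)

    @given(st.lists(st.floats(-100, 100), min_size=8, max_size=8),
           st.lists(st.floats(-100, 100), min_size=8, max_size=8))
    def test_matches_direct_formula(self, obs, pred):
        obs, pred = np.array(obs), np.array(pred)
        w = np.array([4, 1, 1, 1, 1, 1, 1, 2.0])
        expected = float(np.sum(w * (obs - pred) ** 2))
        assert weighted_sse(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_masked_positions_dropped_with_weights(self):
        obs = np.array([1.0, np.nan, 1, 1, 1, 1, 1, 1])
        assert weighted_sse(obs, np.zeros(8)) == pytest.approx(11.0)

    def test_all_masked_undefined(self):
        assert np.isnan(weighted_sse(np.full(8, np.nan), np.zeros(8)))


class TestLinearFit:
    def test_exact_line_recovery(self):
        y = np.arange(1, 9) * 25.0
        fit = fit_model(y, "linear", 500.0, seed=0, **FAST)
        assert fit.params.omega_diff_ms == pytest.approx(25.0, abs=0.01)
        assert fit.rmse_ms < 1e-6

    def test_bounds_respected(self):
        y = np.arange(1, 9) * 500.0  # slope far beyond the box
        fit = fit_model(y, "linear", 500.0, seed=0, **FAST)
        assert fit.params.omega2_ms <= 800.0 + 1e-9
        assert fit.boundary_hit["omega2"]

    def test_sklearn_interface(self):
        X = np.arange(1, 9).reshape(-1, 1)
        y = (X[:, 0] * 10.0) + 3 * np.sin(X[:, 0])
        est = LinearDriftRegressor(omega1_ms=500.0, random_state=0,
                                   n_restarts=2, population=8, generations=15)
        est.fit(X, y)
        assert est.omega_diff_ == pytest.approx(10.0, abs=1.0)
        pred = est.predict(X)
        assert pred.shape == (8,)
        params = est.get_params()
        assert params["omega1_ms"] == 500.0


class TestDelayCoupledFit:
    def test_noise_free_recovery_fixed_tau(self):
        for kappa, wd in [(3.0, 40.0), (6.0, -60.0)]:
            p = OscParams.from_diff(500, wd, kappa=kappa, tau_ms=10.15)
            y = simulate_delay_coupled(p).asynchronies_ms
            fit = refit_fixed_tau(y, 500.0, 10.15, seed=7, n_restarts=10,
                                  population=16, generations=30)
            assert fit.params.kappa == pytest.approx(kappa, rel=0.05)
            assert fit.params.omega_diff_ms == pytest.approx(wd, abs=1.0)

    def test_fixed_tau_is_clamped_exactly(self):
        y = np.arange(1, 9) * 5.0
        fit = refit_fixed_tau(y, 500.0, 12.5, seed=0, **FAST)
        assert fit.params.tau_ms == 12.5

    def test_nested_weighted_sse_never_worse_than_linear(self, rng):
        for _ in range(5):
            y = rng.normal(0, 30, 8) + np.arange(1, 9) * rng.uniform(-40, 40)
            lin = fit_model(y, "linear", 500.0, seed=3, **FAST)
            dc = refit_fixed_tau(y, 500.0, 10.15, seed=3, **FAST)
            assert dc.weighted_sse <= lin.weighted_sse * (1 + 1e-9) + 1e-9

    def test_seed_reproducibility(self):
        y = np.array([5.0, 12, 17, 20, 22, 23, 25, 24])
        a = refit_fixed_tau(y, 500.0, 10.15, seed=42, **FAST)
        b = refit_fixed_tau(y, 500.0, 10.15, seed=42, **FAST)
        assert a.params == b.params
        assert a.rmse_ms == b.rmse_ms

    def test_restart_winner_monotone(self):
        """Best-of-n RMSE can only improve as restarts accumulate."""
        y = np.array([30.0, 42, 55, 61, 70, 74, 81, 85]) + \
            np.array([3.0, -2, 1, -4, 2, 0, -1, 2])
        rmses = []
        for n in (1, 2, 4):
            fit = refit_fixed_tau(y, 500.0, 10.15, seed=5, n_restarts=n,
                                  population=12, generations=20)
            rmses.append(fit.rmse_ms)
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_sklearn_interface_and_predict(self):
        p = OscParams.from_diff(500, 30, kappa=5, tau_ms=10.15)
        y = simulate_delay_coupled(p).asynchronies_ms
        est = DelayCoupledRegressor(
            omega1_ms=500.0, bounds=FitBounds(fixed_tau_ms=10.15),
            random_state=0, n_restarts=3, population=16, generations=30)
        X = np.arange(1, 9).reshape(-1, 1)
        est.fit(X, y)
        assert est.kappa_ == pytest.approx(5.0, rel=0.1)
        assert np.max(np.abs(est.predict(X) - y)) < 1.0
        assert est.score(X, y) > 0.99


class TestBoundaryHits:
    def test_within_tolerance_flagged(self):
        b = FitBounds()
        p = OscParams(500, 500, kappa=49.995, tau_ms=10)
        assert detect_boundary_hits(p, b)["kappa"]

    def test_outside_tolerance_not_flagged(self):
        b = FitBounds()
        p = OscParams(500, 500, kappa=49.9, tau_ms=10)
        assert not detect_boundary_hits(p, b)["kappa"]

    def test_flag_iff_within_001_on_grid(self):
        b = FitBounds()
        for kappa in np.linspace(49.9, 50.0, 41):
            flags = detect_boundary_hits(OscParams(500, 500, kappa=kappa), b)
            assert flags["kappa"] == (abs(kappa - 50.0) < 0.01)

    def test_omega2_flagged_at_either_edge(self):
        b = FitBounds()
        assert detect_boundary_hits(OscParams(500, 200.005), b)["omega2"]
        assert detect_boundary_hits(OscParams(500, 799.995), b)["omega2"]
        assert not detect_boundary_hits(OscParams(500, 500.0), b)["omega2"]


class TestMedianTau:
    def _fit(self, tau, boundary=False):
        from tapsync.estimators import FitResult
        kappa = 49.9999 if boundary else 5.0
        params = OscParams(500, 510, kappa=kappa, tau_ms=tau)
        return FitResult("delay_coupled", params, 1.0, 1.0,
                         detect_boundary_hits(params, FitBounds()), 1, 0, 0)

    def test_two_point_median(self):
        assert median_tau([self._fit(10.0), self._fit(10.3)]) == pytest.approx(10.15)

    def test_odd_count_middle_order_statistic(self):
        fits = [self._fit(t) for t in (30.0, 5.0, 12.0)]
        assert median_tau(fits) == 12.0

    def test_boundary_fits_excluded(self):
        fits = [self._fit(10.0), self._fit(10.3), self._fit(49.0, boundary=True)]
        assert median_tau(fits) == pytest.approx(10.15)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_tau([])


class TestMaskedFitting:
    def test_fit_with_masked_positions(self):
        y = np.arange(1, 9) * 20.0
        y[2] = np.nan
        fit = fit_model(y, "linear", 500.0, seed=0, **FAST)
        assert fit.params.omega_diff_ms == pytest.approx(20.0, abs=0.05)

    def test_series_object_accepted(self):
        s = AsynchronySeries.from_values(np.arange(1, 9) * 15.0)
        fit = fit_model(s, "linear", 500.0, seed=0, **FAST)
        assert fit.params.omega_diff_ms == pytest.approx(15.0, abs=0.05)
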