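"""Estimators fitting oscillator models to 8-position asynchrony series.

Two scikit-learn-style regressors are provided.  ``X`` is a column of 1-based
serial positions (the melody events within a turn) and ``y`` the observed
signed asynchronies in ms at those positions; NaNs in ``y`` mark missing
positions and are excluded (with their weights) from the objective.

* :class:`LinearDriftRegressor` — constant-period drift, only the intrinsic
  period ``omega2`` free.
* :class:`DelayCoupledRegressor` — the delay-coupled model with coupling
  ``kappa``, intrinsic period ``omega2`` and (optionally fixed) delay ``tau``
  free.

Both minimize a weighted sum of squared errors in which the first serial
position is weighted 4 and the last 2 (the turn onset behaves like a
perturbation, so the early curvature of the asynchrony series carries most of
the model-discriminating information).  Each fit runs ``n_restarts``
independent two-stage searches — a seeded population-based global stage
(differential evolution) followed by bounded L-BFGS-B refinement — and keeps
the restart with the lowest *plain* RMSE over the available positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import AsynchronySeries
from .simulate import OscParams, SimConfig, _integrate_dc

__all__ = [
    "FitBounds",
    "FitResult",
    "LinearDriftRegressor",
    "DelayCoupledRegressor",
    "position_weights",
    "weighted_sse",
    "fit_model",
    "refit_fixed_tau",
    "median_tau",
    "detect_boundary_hits",
    "BOUNDARY_TOL_MS",
]

#: a parameter within this distance of its bound counts as a boundary hit
BOUNDARY_TOL_MS = 0.01


def position_weights(n_positions: int = 8) -> np.ndarray:
    """Objective weights over serial positions: 4 at position 1, 2 at the last."""
    w = np.ones(n_positions)
    w[0] = 4.0
    if n_positions > 1:
        w[-1] = 2.0
    return w


def _values_mask(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, AsynchronySeries):
        return series.values, series.missing_mask
    values = np.asarray(series, dtype=float)
    return values, ~np.isfinite(values)


def weighted_sse(observed, predicted, weights: np.ndarray | None = None) -> float:
    """Weighted sum of squared errors between two equal-length series.

    Masked (NaN) positions in either series are excluded together with their
    weights; if every position is masked the objective is undefined (NaN).
    """
    obs, obs_mask = _values_mask(observed)
    pred, pred_mask = _values_mask(predicted)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted series must have equal length")
    if weights is None:
        weights = position_weights(obs.size)
    keep = ~(obs_mask | pred_mask)
    if not np.any(keep):
        return float("nan")
    r = obs[keep] - pred[keep]
    return float(np.sum(weights[keep] * r * r))


def _plain_rmse(obs, pred, keep) -> float:
    if not np.any(keep):
        return float("nan")
    r = obs[keep] - pred[keep]
    return float(np.sqrt(np.mean(r * r)))


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the model parameters.

    ``omega2`` is bounded to the cue period +/- ``omega2_halfwidth_ms``
    (300 ms by default, widened to 350 ms for pairs whose spontaneous rates
    differ by more than 300 ms).  ``fixed_tau_ms`` clamps the delay instead of
    searching it.
    """

    kappa: tuple[float, float] = (0.0, 50.0)
    tau: tuple[float, float] = (0.0, 50.0)
    omega2_halfwidth_ms: float = 300.0
    fixed_tau_ms: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.kappa, self.tau):
            if lo > hi:
                raise ValueError("lower bound exceeds upper bound")
        if self.omega2_halfwidth_ms <= 0:
            raise ValueError("omega2_halfwidth_ms must be positive")

    def omega2(self, omega1_ms: float) -> tuple[float, float]:
        lo = omega1_ms - self.omega2_halfwidth_ms
        hi = omega1_ms + self.omega2_halfwidth_ms
        # an oscillator period must stay positive
        return (max(lo, 1.0), hi)


@dataclass
class FitResult:
    """Outcome of one trial x model fit."""

    model_type: str  # "delay_coupled" | "linear"
    params: OscParams
    weighted_sse: float
    rmse_ms: float
    boundary_hit: dict = field(default_factory=dict)
    n_restarts: int = 0
    best_restart_index: int = -1
    seed: int | None = None
    failed: bool = False

    @property
    def any_boundary_hit(self) -> bool:
        return any(self.boundary_hit.values())


def detect_boundary_hits(params: OscParams, bounds: FitBounds,
                         model_type: str = "delay_coupled") -> dict:
    """Per-parameter ceiling flags: within 0.01 of a relevant bound.

    ``kappa`` and ``tau`` are flagged at their upper bound only (their lower
    bound, 0, is the meaningful "no coupling"/"no delay" value); ``omega2`` is
    flagged at either edge of its box.  A clamped ``tau`` is never flagged.
    """
    o2lo, o2hi = bounds.omega2(params.omega1_ms)
    flags = {
        "omega2": (abs(params.omega2_ms - o2lo) < BOUNDARY_TOL_MS
                   or abs(params.omega2_ms - o2hi) < BOUNDARY_TOL_MS),
    }
    if model_type == "delay_coupled":
        flags["kappa"] = abs(params.kappa - bounds.kappa[1]) < BOUNDARY_TOL_MS
        if bounds.fixed_tau_ms is None:
            flags["tau"] = abs(params.tau_ms - bounds.tau[1]) < BOUNDARY_TOL_MS
    return flags


def _check_X_y(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError("X must be a single column of serial positions")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("X and y length mismatch")
    positions = X[:, 0]
    if np.any(positions < 1) or np.any(positions != np.round(positions)):
        raise ValueError("serial positions must be positive integers")
    return positions.astype(int), y


class _OscFitMixin:
    """Shared fit machinery: seeded restarts of DE + bounded local refinement."""

    def _restart_seeds(self, n_restarts: int) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        return rng.integers(0, 2**31 - 1, size=n_restarts)

    def _run_restarts(self, objective, bounds_list, init_extra, n_restarts,
                      popsize, maxiter, rmse_of):
        """Return (best_x, best_sse, best_rmse, best_index).

        ``init_extra`` rows are injected into every restart's initial
        population (e.g. the linear model's closed-form optimum), which makes
        the nested delay-coupled fit at least as good as the linear fit.
        """
        lo = np.array([b[0] for b in bounds_list])
        hi = np.array([b[1] for b in bounds_list])
        ndim = len(bounds_list)
        npop = max(popsize, 5)
        best = None
        seeds = self._restart_seeds(n_restarts)
        for i, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            init = lo + (hi - lo) * rng.random((npop, ndim))
            for j, row in enumerate(init_extra):
                init[j % npop] = np.clip(row, lo, hi)
            try:
                res = differential_evolution(
                    objective, bounds_list, init=init, maxiter=maxiter,
                    seed=int(seed), polish=False, tol=0.01)
                loc = minimize(objective, np.clip(res.x, lo, hi),
                               method="L-BFGS-B", bounds=bounds_list)
                x = loc.x if loc.fun <= res.fun else res.x
                sse = min(float(loc.fun), float(res.fun))
            except Exception:  # noqa: BLE001 - a failed restart is dropped
                continue
            if not np.isfinite(sse):
                continue
            rmse = rmse_of(x)
            if best is None or rmse < best[2]:
                best = (x, sse, rmse, i)
        return best


class LinearDriftRegressor(_OscFitMixin, RegressorMixin, BaseEstimator):
    """Constant-period drift model: ``a(k) = a0 + k * (omega2 - omega1)``.

    Only ``omega2`` is free; the drift slope per serial position is the
    intrinsic-rate difference.  The weighted objective is quadratic in
    ``omega2`` so the closed-form weighted least-squares optimum is injected
    into every restart and the fit is exact up to float precision.

    Parameters
    ----------
    omega1_ms : float
        Cue period (driver rate), fixed.
    bounds : FitBounds
        Box constraints; only the ``omega2`` box applies.
    a0_ms : float
        Fixed initial asynchrony (0: aligned at the turn onset).
    n_restarts, population, generations : int
        Search effort per fit (kept for interface symmetry; one restart
        already finds the quadratic optimum).
    random_state : int or None
        Seeds every stochastic component of the search.
    """

    _model_type = "linear"

    def __init__(self, omega1_ms: float = 500.0, bounds: FitBounds = FitBounds(),
                 a0_ms: float = 0.0, n_restarts: int = 10, population: int = 40,
                 generations: int = 80, random_state: int | None = None):
        self.omega1_ms = omega1_ms
        self.bounds = bounds
        self.a0_ms = a0_ms
        self.n_restarts = n_restarts
        self.population = population
        self.generations = generations
        self.random_state = random_state

    def _predict_positions(self, omega2: float, positions: np.ndarray) -> np.ndarray:
        return self.a0_ms + positions * (omega2 - self.omega1_ms)

    def fit(self, X, y):
        positions, y = _check_X_y(X, y)
        keep = np.isfinite(y)
        if not np.any(keep):
            raise ValueError("all positions are masked")
        w = position_weights(positions.max())[positions - 1]
        o2b = self.bounds.omega2(self.omega1_ms)

        def objective(x):
            r = y[keep] - self._predict_positions(x[0], positions[keep])
            return float(np.sum(w[keep] * r * r))

        def rmse_of(x):
            return _plain_rmse(y, self._predict_positions(x[0], positions), keep)

        # closed-form weighted least squares for the slope
        k = positions[keep].astype(float)
        resid = y[keep] - self.a0_ms
        slope = np.sum(w[keep] * k * resid) / np.sum(w[keep] * k * k)
        exact = np.clip(self.omega1_ms + slope, o2b[0], o2b[1])
        best = self._run_restarts(objective, [o2b], [np.array([exact])],
                                  self.n_restarts, self.population,
                                  self.generations, rmse_of)
        if best is None:
            raise RuntimeError("all restarts failed")
        x, sse, rmse, idx = best
        self.omega2_ = float(x[0])
        self.omega_diff_ = self.omega2_ - self.omega1_ms
        self.weighted_sse_ = sse
        self.rmse_ = rmse
        self.best_restart_ = idx
        self.params_ = OscParams(self.omega1_ms, self.omega2_, 0.0, 0.0, self.a0_ms)
        self.boundary_hit_ = detect_boundary_hits(self.params_, self.bounds, "linear")
        return self

    def predict(self, X):
        positions = np.asarray(X, dtype=float).reshape(-1)
        return self._predict_positions(self.omega2_, positions)


class DelayCoupledRegressor(_OscFitMixin, RegressorMixin, BaseEstimator):
    """Delay-coupled phase-oscillator model fit to an asynchrony series.

    Free parameters are the coupling strength ``kappa``, the intrinsic period
    ``omega2`` and, unless ``bounds.fixed_tau_ms`` is set, the self-feedback
    delay ``tau``.  Predictions come from forward DDE integration with the
    driven phase re-initialized at the turn onset (asynchrony ``a0_ms`` at the
    virtual event 0).

    Fitted attributes: ``kappa_``, ``omega2_``, ``omega_diff_``, ``tau_``,
    ``weighted_sse_``, ``rmse_``, ``boundary_hit_``, ``params_``,
    ``best_restart_``.
    """

    _model_type = "delay_coupled"

    def __init__(self, omega1_ms: float = 500.0, bounds: FitBounds = FitBounds(),
                 a0_ms: float = 0.0, n_restarts: int = 10, population: int = 40,
                 generations: int = 80, step_ms: float = 1.0,
                 random_state: int | None = None):
        self.omega1_ms = omega1_ms
        self.bounds = bounds
        self.a0_ms = a0_ms
        self.n_restarts = n_restarts
        self.population = population
        self.generations = generations
        self.step_ms = step_ms
        self.random_state = random_state

    def _simulate(self, kappa: float, omega2: float, tau: float,
                  n_events: int) -> np.ndarray:
        out, unstable = _integrate_dc(float(self.omega1_ms), float(omega2),
                                      float(kappa), float(tau), float(self.a0_ms),
                                      int(n_events), float(self.step_ms))
        if unstable:
            return np.full(n_events, np.nan)
        return out

    def fit(self, X, y):
        positions, y = _check_X_y(X, y)
        keep = np.isfinite(y)
        if not np.any(keep):
            raise ValueError("all positions are masked")
        n_events = int(positions.max())
        w = position_weights(n_events)[positions - 1]
        o2b = self.bounds.omega2(self.omega1_ms)
        fixed_tau = self.bounds.fixed_tau_ms
        free_tau = fixed_tau is None

        def unpack(x):
            if free_tau:
                return x[0], x[1], x[2]
            return x[0], x[1], fixed_tau

        def objective(x):
            kappa, omega2, tau = unpack(x)
            pred = self._simulate(kappa, omega2, tau, n_events)[positions - 1]
            ok = keep & np.isfinite(pred)
            if not np.any(ok):
                return 1e15
            r = y[ok] - pred[ok]
            sse = float(np.sum(w[ok] * r * r))
            if np.any(keep & ~np.isfinite(pred)):  # diverged inside the window
                sse += 1e12
            return sse

        def rmse_of(x):
            kappa, omega2, tau = unpack(x)
            pred = self._simulate(kappa, omega2, tau, n_events)[positions - 1]
            return _plain_rmse(y, pred, keep & np.isfinite(pred))

        bounds_list = [self.bounds.kappa, o2b]
        if free_tau:
            bounds_list.append(self.bounds.tau)
        # seed the population with the linear model's exact optimum (kappa=0)
        k = positions[keep].astype(float)
        resid = y[keep] - self.a0_ms
        slope = np.sum(w[keep] * k * resid) / np.sum(w[keep] * k * k)
        lin = [0.0, np.clip(self.omega1_ms + slope, o2b[0], o2b[1])]
        if free_tau:
            lin.append(self.bounds.tau[0])
        best = self._run_restarts(objective, bounds_list, [np.array(lin)],
                                  self.n_restarts, self.population,
                                  self.generations, rmse_of)
        if best is None:
            raise RuntimeError("all restarts failed")
        x, sse, rmse, idx = best
        kappa, omega2, tau = unpack(x)
        self.kappa_ = float(kappa)
        self.omega2_ = float(omega2)
        self.omega_diff_ = self.omega2_ - self.omega1_ms
        self.tau_ = float(tau)
        self.weighted_sse_ = sse
        self.rmse_ = rmse
        self.best_restart_ = idx
        self.params_ = OscParams(self.omega1_ms, self.omega2_, self.kappa_,
                                 self.tau_, self.a0_ms)
        self.boundary_hit_ = detect_boundary_hits(self.params_, self.bounds,
                                                  "delay_coupled")
        return self

    def predict(self, X):
        positions = np.asarray(X, dtype=float).reshape(-1).astype(int)
        n_events = int(positions.max())
        pred = self._simulate(self.kappa_, self.omega2_, self.tau_, n_events)
        return pred[positions - 1]


# ---------------------------------------------------------------------------
# functional wrappers used by the pipeline


def _series_xy(series) -> tuple[np.ndarray, np.ndarray]:
    values, mask = _values_mask(series)
    X = np.arange(1, values.size + 1).reshape(-1, 1)
    y = values.copy()
    y[mask] = np.nan
    return X, y


def fit_model(series, model_type: str, omega1_ms: float,
              bounds: FitBounds = FitBounds(), n_restarts: int = 10,
              seed: int | None = None, population: int = 40,
              generations: int = 80, step_ms: float = 1.0) -> FitResult:
    """Fit one model to one averaged asynchrony series and wrap the result."""
    X, y = _series_xy(series)
    if model_type == "linear":
        est = LinearDriftRegressor(omega1_ms=omega1_ms, bounds=bounds,
                                   n_restarts=n_restarts, population=population,
                                   generations=generations, random_state=seed)
    elif model_type == "delay_coupled":
        est = DelayCoupledRegressor(omega1_ms=omega1_ms, bounds=bounds,
                                    n_restarts=n_restarts, population=population,
                                    generations=generations, step_ms=step_ms,
                                    random_state=seed)
    else:
        raise ValueError(f"unknown model_type: {model_type!r}")
    try:
        est.fit(X, y)
    except RuntimeError:
        return FitResult(model_type, OscParams(omega1_ms, omega1_ms),
                         float("nan"), float("nan"), {}, n_restarts, -1, seed,
                         failed=True)
    return FitResult(model_type, est.params_, est.weighted_sse_, est.rmse_,
                     est.boundary_hit_, n_restarts, est.best_restart_, seed)


def refit_fixed_tau(series, omega1_ms: float, fixed_tau_ms: float,
                    bounds: FitBounds = FitBounds(), **kwargs) -> FitResult:
    """Delay-coupled refit with the delay clamped (only kappa, omega2 free)."""
    clamped = FitBounds(kappa=bounds.kappa, tau=bounds.tau,
                        omega2_halfwidth_ms=bounds.omega2_halfwidth_ms,
                        fixed_tau_ms=fixed_tau_ms)
    return fit_model(series, "delay_coupled", omega1_ms, bounds=clamped, **kwargs)


def median_tau(fits) -> float:
    """Median fitted delay over free-tau fits, boundary-hit fits excluded."""
    taus = [f.params.tau_ms for f in fits
            if f.model_type == "delay_coupled" and not f.failed
            and not f.any_boundary_hit]
    if not taus:
        raise ValueError("no usable free-tau fits")
    return float(np.median(taus))
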