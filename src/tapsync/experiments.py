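"""Reproducible benchmark experiments for the package's core claims.

Each function generates its own data from a seed, runs the relevant part of
the pipeline, and returns measured quantities.  They are used both by the
test suite and by ``scripts/acceptance.py``.

Problem sizes follow the package's validation protocol: 100 parameter draws
for the no-coupling reduction, a 60-point stable grid for integrator
convergence, 50 trials for parameter recovery at the reference search budget,
200 trials for regime classification, and the full default 12-pair experiment
for the train/test/surrogate comparison (reduced search preset; the measured
orderings are insensitive to the remaining optimizer slack).
"""

from __future__ import annotations

import numpy as np

from .estimators import fit_model, refit_fixed_tau
from .pipeline import FitConfig, run_pipeline
from .report import classify_trial
from .simulate import OscParams, SimConfig, simulate_delay_coupled, simulate_linear
from .synth import ExperimentDesign, generate_experiment

__all__ = [
    "kappa_zero_reduction",
    "anticipation_convergence",
    "step_convergence",
    "parameter_recovery",
    "noise_free_recovery",
    "classification_agreement",
    "pipeline_cross_validation",
]

REFERENCE_TAU_MS = 10.15


def kappa_zero_reduction(seed: int = 0, n_draws: int = 100) -> dict:
    """Max |delay-coupled - linear| over random parameter draws at kappa=0."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        p = OscParams.from_diff(rng.uniform(305, 838), rng.uniform(-300, 300),
                                kappa=0.0, tau_ms=rng.uniform(0, 50),
                                a0_ms=rng.uniform(-50, 50))
        dc = simulate_delay_coupled(p).asynchronies_ms
        lin = simulate_linear(p).asynchronies_ms
        worst = max(worst, float(np.max(np.abs(dc - lin))))
    return {"max_abs_diff_ms": worst, "n": n_draws}


def anticipation_convergence(n_events: int = 200, tau_ms: float = 10.0,
                             kappa: float = 5.0,
                             omega1_ms: float = 500.0) -> dict:
    """Long-run asynchrony with matched rates; converges to -tau."""
    p = OscParams.from_diff(omega1_ms, 0.0, kappa=kappa, tau_ms=tau_ms)
    out = simulate_delay_coupled(p, SimConfig(n_events=n_events))
    final = float(out.asynchronies_ms[-1])
    return {"asynchrony_ms": final,
            "rel_err_pct": abs(final + tau_ms) / tau_ms * 100.0,
            "n": n_events}


def step_convergence(step_coarse: float = 1.0, step_fine: float = 0.01) -> dict:
    """Worst per-position change between coarse and fine integration steps."""
    worst = 0.0
    n = 0
    for kappa in (1.0, 5.0, 20.0, 50.0):
        for wd in (-200.0, -50.0, 0.0, 50.0, 200.0):
            for tau in (0.5, 10.15, 50.0):
                p = OscParams.from_diff(500.0, wd, kappa=kappa, tau_ms=tau)
                a = simulate_delay_coupled(p, SimConfig(step_ms=step_coarse))
                b = simulate_delay_coupled(p, SimConfig(step_ms=step_fine))
                worst = max(worst, float(np.nanmax(
                    np.abs(a.asynchronies_ms - b.asynchronies_ms))))
                n += 1
    return {"max_abs_diff_ms": worst, "n": n}


def _averaged_noisy_series(true_series: np.ndarray, noise_sd: float,
                           n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Repetition-averaged observation: per-tap motor noise averaged over turns."""
    noise = rng.normal(0.0, noise_sd, (n_reps, true_series.size))
    return true_series + noise.mean(axis=0)


def parameter_recovery(seed: int = 0, n_trials: int = 50,
                       noise_sd_ms: float = 10.0, n_reps: int = 4,
                       config: FitConfig | None = None) -> dict:
    """Recover (kappa, omega_diff) from noisy averaged series, delay fixed.

    True kappa is uniform on [2, 8] and omega_diff uniform on [-80, 80] ms
    (cue period 500 ms); each trial observes the model series through
    ``n_reps`` repetitions of additive Gaussian motor noise, averaged, as the
    pipeline observes real trials.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    kappa_rel, wd_abs = [], []
    for _ in range(n_trials):
        kappa = rng.uniform(2.0, 8.0)
        wd = rng.uniform(-80.0, 80.0)
        p = OscParams.from_diff(500.0, wd, kappa=kappa,
                                tau_ms=REFERENCE_TAU_MS)
        y = _averaged_noisy_series(
            simulate_delay_coupled(p).asynchronies_ms, noise_sd_ms, n_reps, rng)
        fit = refit_fixed_tau(y, 500.0, REFERENCE_TAU_MS,
                              n_restarts=config.n_restarts,
                              seed=int(rng.integers(2**31 - 1)),
                              population=config.population,
                              generations=config.generations)
        kappa_rel.append(abs(fit.params.kappa - kappa) / kappa)
        wd_abs.append(abs(fit.params.omega_diff_ms - wd))
    return {"kappa_median_rel_err_pct": float(np.median(kappa_rel)) * 100.0,
            "omega_diff_median_abs_err_ms": float(np.median(wd_abs)),
            "n": n_trials}


def noise_free_recovery(seed: int = 0, config: FitConfig | None = None) -> dict:
    """Exact-model recovery without noise: worst-case errors over a small grid."""
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    worst_kappa, worst_wd = 0.0, 0.0
    cases = [(3.0, 40.0), (6.0, -60.0), (2.5, 75.0), (7.5, -20.0)]
    for kappa, wd in cases:
        p = OscParams.from_diff(500.0, wd, kappa=kappa, tau_ms=REFERENCE_TAU_MS)
        y = simulate_delay_coupled(p).asynchronies_ms
        fit = refit_fixed_tau(y, 500.0, REFERENCE_TAU_MS,
                              n_restarts=config.n_restarts,
                              seed=int(rng.integers(2**31 - 1)),
                              population=config.population,
                              generations=config.generations)
        worst_kappa = max(worst_kappa, abs(fit.params.kappa - kappa) / kappa)
        worst_wd = max(worst_wd, abs(fit.params.omega_diff_ms - wd))
    return {"kappa_max_rel_err_pct": worst_kappa * 100.0,
            "omega_diff_max_abs_err_ms": worst_wd, "n": len(cases)}


def classification_agreement(seed: int = 0, n_trials: int = 200,
                             noise_sd_ms: float = 10.0, n_reps: int = 4,
                             config: FitConfig | None = None) -> dict:
    """Trial-level coupled/uncoupled agreement with the generating regime.

    Half the trials are coupled (kappa uniform on [2, 8]) and half drift
    without coupling (kappa = 0); both share omega_diff uniform on
    [-80, 80] ms.  ``noise_sd_ms = 0`` measures the noise-free rule.
    """
    config = config or FitConfig.fast()
    rng = np.random.default_rng(seed)
    correct = 0
    for i in range(n_trials):
        coupled = i % 2 == 0
        wd = rng.uniform(-80.0, 80.0)
        kappa = rng.uniform(2.0, 8.0) if coupled else 0.0
        p = OscParams.from_diff(500.0, wd, kappa=kappa,
                                tau_ms=REFERENCE_TAU_MS if coupled else 0.0)
        if coupled:
            true = simulate_delay_coupled(p).asynchronies_ms
        else:
            true = simulate_linear(p).asynchronies_ms
        if noise_sd_ms > 0:
            y = _averaged_noisy_series(true, noise_sd_ms, n_reps, rng)
        else:
            y = true.copy()
        lin = fit_model(y, "linear", 500.0, n_restarts=config.n_restarts,
                        seed=int(rng.integers(2**31 - 1)),
                        population=config.population,
                        generations=config.generations)
        dc = refit_fixed_tau(y, 500.0, REFERENCE_TAU_MS,
                             n_restarts=config.n_restarts,
                             seed=int(rng.integers(2**31 - 1)),
                             population=config.population,
                             generations=config.generations)
        if classify_trial(lin, dc) == coupled:
            correct += 1
    return {"agreement_pct": correct / n_trials * 100.0, "n": n_trials}


def pipeline_cross_validation(seed: int = 0,
                              design: ExperimentDesign | None = None,
                              config: FitConfig | None = None) -> dict:
    """Full pipeline on a default synthetic experiment.

    Returns the train/test/surrogate RMSE and z means, the median fitted
    delay, nested-model violations, design counts and classification
    agreement against the generator's ground truth.
    """
    config = config or FitConfig.fast()
    design = design or ExperimentDesign(seed=seed)
    exp = generate_experiment(design)
    res = run_pipeline(exp.trials, seed=seed + 1, fit_config=config,
                       ratings=exp.ratings_frame())
    cv = res.cv_frame()
    means = cv[["rmse_train", "rmse_test", "rmse_surrogate"]].mean()
    zs = cv[["z_test", "z_surrogate"]].mean()

    # nested-model check over every trial fitted with both models
    violations = 0
    fitted = 0
    for key in res.trial_labels:
        dc = res.fits.get((key, "delay_coupled", "fixed_tau")) or \
            res.fits.get((key, "delay_coupled", "free_tau"))
        lin = res.fits[(key, "linear", "full")]
        fitted += 1
        if dc.weighted_sse > lin.weighted_sse * (1 + 1e-9) + 1e-9:
            violations += 1

    gt = exp.ground_truth_frame()
    agree = []
    for _, r in gt.iterrows():
        key = (r.pair_id, r.participant_id, r.task, r.cued_rate, r.trial_index)
        if key in res.trial_labels:
            agree.append(res.trial_labels[key] == r.coupled)
    per_participant = {}
    for t in exp.sync_trials:
        per_participant[t.participant_id] = \
            per_participant.get(t.participant_id, 0) + 1
    series_len = design.melody_length

    return {
        "rmse_train_ms": float(means["rmse_train"]),
        "rmse_test_ms": float(means["rmse_test"]),
        "rmse_surrogate_ms": float(means["rmse_surrogate"]),
        "z_test": float(zs["z_test"]),
        "z_surrogate": float(zs["z_surrogate"]),
        "median_tau_ms": float(res.median_tau_ms),
        "nested_violations": violations,
        "n_fitted": fitted,
        "n_sync_trials": len(exp.sync_trials),
        "trials_per_participant": int(max(per_participant.values())),
        "series_length": series_len,
        "uncoupled_trials": res.counts["uncoupled_trials"],
        "ground_truth_agreement_pct": float(np.mean(agree)) * 100.0,
        "counts": res.counts,
        "result": res,
    }
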