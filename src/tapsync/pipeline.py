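"""End-to-end analysis: preprocess, fit, cross-validate, classify, summarize.

The stages mirror the analysis a synchronization study runs on its event
data:

1. average each synchronization trial's four tapped repetitions into one
   8-position asynchrony series (trials with too many missing positions are
   excluded);
2. fit the delay-coupled model with the time delay free, take the median
   fitted delay over clean (non-boundary) fits, and refit every trial with
   the delay fixed at that median; fit the drift-only linear model;
3. classify every trial, participant and pair as coupled/uncoupled from the
   RMSE comparison of the two models;
4. cross-validate: fit both models to each trial's Train half ({1,3} or
   {2,4} repetition average, balanced within participant), score the frozen
   predictions on the Test half and on condition-matched surrogate series
   from the other pairs;
5. tabulate condition summaries, social-rating medians by coupling class,
   and an exclusion-accounting of every generated trial.

Pairs whose members' spontaneous rates differ by more than 300 ms get a
widened intrinsic-period search box (+/- 350 ms) in every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crossval import (
    CVRecord,
    assign_balanced_splits,
    build_surrogates,
    evaluate_on_test,
    score_surrogates,
    split_train_test,
)
from .datatypes import CuedRate, Task
from .estimators import FitBounds, FitResult, fit_model, median_tau
from .preprocess import (
    MAX_MASKED_POSITIONS,
    average_repetitions,
    compute_spr,
    variability_indices,
)
from .report import (
    classify_pair,
    classify_participant,
    classify_trial,
    condition_summary,
    ratings_summary,
)

__all__ = ["FitConfig", "PipelineResult", "run_pipeline", "WIDE_PAIR_THRESHOLD_MS"]

#: pairs with |SPR difference| above this get the widened omega2 box
WIDE_PAIR_THRESHOLD_MS = 300.0
WIDE_PAIR_HALFWIDTH_MS = 350.0


@dataclass(frozen=True)
class FitConfig:
    """Search effort per model fit.

    The reference setting (10 restarts, population 40, 80 generations)
    matches the fitting procedure's defaults; :meth:`fast` is a reduced
    preset for the full-pipeline stages, where the quantities of interest
    (orderings, classification rates) are insensitive to the remaining
    optimizer slack.
    """

    n_restarts: int = 10
    population: int = 40
    generations: int = 80
    step_ms: float = 1.0

    @classmethod
    def fast(cls) -> "FitConfig":
        return cls(n_restarts=3, population=16, generations=30)

    def fit(self, series, model_type, omega1_ms, bounds, seed) -> FitResult:
        return fit_model(series, model_type, omega1_ms, bounds=bounds,
                         n_restarts=self.n_restarts, seed=seed,
                         population=self.population,
                         generations=self.generations, step_ms=self.step_ms)


@dataclass
class PipelineResult:
    fits: dict  # (trial.key, model, stage) -> FitResult
    median_tau_ms: float
    trial_labels: dict  # trial.key -> bool (coupled)
    participant_labels: dict  # participant_id -> bool
    pair_labels: dict  # pair_id -> bool
    cv_records: list  # CVRecord, delay-coupled and linear per trial
    results: pd.DataFrame  # one row per generated synchronization trial
    summary: pd.DataFrame = None
    ratings: pd.DataFrame = None
    counts: dict = field(default_factory=dict)
    spr_ms: dict = field(default_factory=dict)  # participant -> measured SPR

    def cv_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.cv_records:
            pair_id, participant_id, task, cued_rate, trial_index = r.trial_key
            rows.append({
                "pair_id": pair_id, "participant_id": participant_id,
                "task": task, "cued_rate": cued_rate,
                "trial_index": trial_index, "model": r.model_type,
                "train_reps": "".join(map(str, r.assignment)),
                "rmse_train": r.rmse_train, "rmse_test": r.rmse_test,
                "rmse_surrogate": r.rmse_surrogate,
                "r_test": r.r_test, "z_test": r.z_test,
                "r_surrogate": r.r_surrogate, "z_surrogate": r.z_surrogate,
                "n_surrogates": r.n_surrogates,
            })
        return pd.DataFrame(rows)


def _measure_sprs(trials) -> dict:
    """Mean SPR (ms) per participant over non-flagged uncued trials."""
    values: dict = {}
    for t in trials:
        if t.is_synchronization:
            continue
        est = compute_spr(t)
        if not est.flagged:
            values.setdefault(t.participant_id, []).append(est.mean_iti_ms)
    return {pid: float(np.mean(v)) for pid, v in sorted(values.items())}


def _pair_bounds(trials, spr_ms: dict) -> dict:
    """FitBounds per pair; wide pairs get the +/-350 ms intrinsic-rate box."""
    members: dict = {}
    for t in trials:
        members.setdefault(t.pair_id, set()).add(t.participant_id)
    out = {}
    for pair_id, pids in members.items():
        sprs = [spr_ms[p] for p in pids if p in spr_ms]
        wide = (len(sprs) == 2
                and abs(sprs[0] - sprs[1]) > WIDE_PAIR_THRESHOLD_MS)
        out[pair_id] = FitBounds(
            omega2_halfwidth_ms=WIDE_PAIR_HALFWIDTH_MS if wide else 300.0)
    return out


def run_pipeline(trials, seed: int = 0, fit_config: FitConfig | None = None,
                 tau_policy="auto", ratings: pd.DataFrame | None = None,
                 with_cv: bool = True) -> PipelineResult:
    """Run the full analysis over a list of :class:`TrialRecord`.

    ``tau_policy``: ``"auto"`` runs the free-delay stage and refits at the
    median fitted delay; a float skips the free stage and fixes the delay
    directly; ``"free"`` keeps the free-delay fits as final.
    """
    fit_config = fit_config or FitConfig()
    rng = np.random.default_rng(seed)
    sync = sorted((t for t in trials if t.is_synchronization),
                  key=lambda t: t.key)
    spr_ms = _measure_sprs(trials)
    bounds_by_pair = _pair_bounds(sync, spr_ms)

    series = {}
    excluded_masked = set()
    for t in sync:
        s = average_repetitions(t)
        if s.n_missing > MAX_MASKED_POSITIONS:
            excluded_masked.add(t.key)
        else:
            series[t.key] = s

    def trial_seed() -> int:
        return int(rng.integers(2**31 - 1))

    fits: dict = {}
    # stage 1: delay free (skipped when tau_policy is numeric)
    med_tau = float("nan")
    if tau_policy in ("auto", "free"):
        for t in sync:
            if t.key not in series:
                continue
            fits[(t.key, "delay_coupled", "free_tau")] = fit_config.fit(
                series[t.key], "delay_coupled", t.cue_period_ms,
                bounds_by_pair[t.pair_id], trial_seed())
        free = [f for (k, m, st), f in fits.items() if st == "free_tau"]
        try:
            med_tau = median_tau(free)
        except ValueError:
            med_tau = float("nan")
    else:
        med_tau = float(tau_policy)

    # stage 2: final delay-coupled fits (delay fixed unless policy is "free")
    final_stage = "free_tau" if tau_policy == "free" else "fixed_tau"
    for t in sync:
        if t.key not in series:
            continue
        if final_stage == "fixed_tau":
            b = replace(bounds_by_pair[t.pair_id], fixed_tau_ms=med_tau)
            fits[(t.key, "delay_coupled", "fixed_tau")] = fit_config.fit(
                series[t.key], "delay_coupled", t.cue_period_ms, b,
                trial_seed())
        fits[(t.key, "linear", "full")] = fit_config.fit(
            series[t.key], "linear", t.cue_period_ms,
            bounds_by_pair[t.pair_id], trial_seed())

    # stage 3: classification
    trial_labels = {}
    for t in sync:
        if t.key not in series:
            continue
        dc = fits[(t.key, "delay_coupled", final_stage)]
        lin = fits[(t.key, "linear", "full")]
        if dc.failed or lin.failed:
            continue
        trial_labels[t.key] = classify_trial(lin, dc)

    by_participant: dict = {}
    pair_of: dict = {}
    for t in sync:
        pair_of[t.participant_id] = t.pair_id
        if t.key in trial_labels:
            cond = (t.task, t.cued_rate)
            by_participant.setdefault(t.participant_id, {}).setdefault(
                cond, []).append(trial_labels[t.key])
    participant_labels = {pid: classify_participant(conds)
                          for pid, conds in sorted(by_participant.items())}
    members_of: dict = {}
    for pid, pair_id in pair_of.items():
        members_of.setdefault(pair_id, []).append(pid)
    pair_labels = {}
    for pair_id, pids in sorted(members_of.items()):
        labels = [participant_labels[p] for p in sorted(pids)
                  if p in participant_labels]
        if len(labels) == 2:
            pair_labels[pair_id] = classify_pair(labels)

    # stage 4: cross-validation with surrogate baseline
    cv_records = []
    if with_cv:
        cv_keys = [t for t in sync if t.key in series]
        assignments = assign_balanced_splits(cv_keys, rng)
        for t in cv_keys:
            train, test, train_reps = split_train_test(
                t, train_reps=assignments[t.key])
            test_reps = (2, 4) if train_reps == (1, 3) else (1, 3)
            surrogate_series = build_surrogates(sync, t, test_reps, rng)
            for model in ("delay_coupled", "linear"):
                b = bounds_by_pair[t.pair_id]
                if model == "delay_coupled" and np.isfinite(med_tau):
                    b = replace(b, fixed_tau_ms=med_tau)
                train_fit = fit_config.fit(train, model, t.cue_period_ms, b,
                                           trial_seed())
                if train_fit.failed:
                    continue
                r_t, z_t, rmse_t = evaluate_on_test(
                    train_fit, test, step_ms=fit_config.step_ms)
                r_s, z_s, rmse_s, n_s = score_surrogates(
                    train_fit, surrogate_series, step_ms=fit_config.step_ms)
                cv_records.append(CVRecord(
                    trial_key=t.key, model_type=model, assignment=train_reps,
                    train_fit=train_fit, rmse_train=train_fit.rmse_ms,
                    r_test=r_t, z_test=z_t, rmse_test=rmse_t,
                    r_surrogate=r_s, z_surrogate=z_s, rmse_surrogate=rmse_s,
                    n_surrogates=n_s))

    # stage 5: per-trial results table, summaries, accounting
    rows = []
    for t in sync:
        key = t.key
        row = {"pair_id": t.pair_id, "participant_id": t.participant_id,
               "group": t.group.value if hasattr(t.group, "value") else t.group,
               "task": t.task, "cued_rate": t.cued_rate,
               "cue_period_ms": t.cue_period_ms, "trial_index": t.trial_index,
               "excluded_masked": key in excluded_masked}
        if key in series:
            s = series[key]
            vi = variability_indices(t)
            dc = fits.get((key, "delay_coupled", final_stage))
            row.update(mean_asynchrony_ms=float(np.nanmean(s.values)),
                       cv_iti=vi.cv_iti, sd_asynchrony_ms=vi.sd_asynchrony_ms,
                       kappa=dc.params.kappa if dc else float("nan"),
                       omega_diff_ms=dc.params.omega_diff_ms if dc else float("nan"),
                       tau_ms=dc.params.tau_ms if dc else float("nan"),
                       rmse_dc=dc.rmse_ms if dc else float("nan"),
                       rmse_linear=fits[(key, "linear", "full")].rmse_ms,
                       boundary_hit=dc.any_boundary_hit if dc else True,
                       coupled=trial_labels.get(key),
                       retained=key in trial_labels)
        else:
            row.update(mean_asynchrony_ms=float("nan"), cv_iti=float("nan"),
                       sd_asynchrony_ms=float("nan"), kappa=float("nan"),
                       omega_diff_ms=float("nan"), tau_ms=float("nan"),
                       rmse_dc=float("nan"), rmse_linear=float("nan"),
                       boundary_hit=False, coupled=None, retained=False)
        rows.append(row)
    results = pd.DataFrame(rows)

    counts = {
        "generated": len(sync),
        "excluded_masked": len(excluded_masked),
        "retained": int(results["retained"].sum()),
        "fit_failed": len(sync) - len(excluded_masked)
        - int(results["retained"].sum()),
        "boundary_flagged": int(results.loc[results["retained"],
                                            "boundary_hit"].sum()),
        "uncoupled_trials": int(sum(not v for v in trial_labels.values())),
        "uncoupled_participants": int(sum(not v for v in
                                          participant_labels.values())),
    }

    summary = condition_summary(results) if len(results) else None
    ratings_table = None
    if ratings is not None and pair_labels:
        ratings_table = ratings_summary(ratings, pair_labels)

    return PipelineResult(fits=fits, median_tau_ms=med_tau,
                          trial_labels=trial_labels,
                          participant_labels=participant_labels,
                          pair_labels=pair_labels, cv_records=cv_records,
                          results=results, summary=summary,
                          ratings=ratings_table, counts=counts, spr_ms=spr_ms)
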