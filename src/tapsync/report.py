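"""Coupled/uncoupled classification, condition summaries, canonical tables.

A trial is *coupled* when the delay-coupled model fits its asynchronies
strictly better (lower RMSE) than the drift-only linear model; a tie or a
linear win means the tapper did not couple with the cue on that trial.  A
participant is *uncoupled* when at least one of the four experimental
conditions (Task x Cued Rate) shows no coupling in any retained trial; a
pair is uncoupled when either member is.

This module also owns the canonical on-disk formats: the long events table
(one row per tap or cue onset) and the tidy fits/CV/labels/summary tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CuedRate, Group, Task, TrialRecord
from .estimators import FitResult

__all__ = [
    "RMSE_TIE_TOL_MS",
    "classify_trial",
    "classify_participant",
    "classify_pair",
    "events_frame",
    "trials_from_events",
    "fits_frame",
    "labels_from_fits_frame",
    "condition_summary",
    "ratings_summary",
]

#: RMSE differences below this are treated as the tie the classification rule
#: sends to "uncoupled" (both optimizers bottom out near machine precision on
#: noise-free drift data, where the strict comparison would be a coin flip)
RMSE_TIE_TOL_MS = 1e-6


def classify_trial(linear_fit: FitResult, dc_fit: FitResult) -> bool:
    """True (coupled) iff the delay-coupled RMSE beats the linear RMSE.

    Ties — including differences below ``RMSE_TIE_TOL_MS`` — count as
    uncoupled: a linear fit as good as the delay-coupled one means no
    evidence of coupling.
    """
    if linear_fit.model_type != "linear" or dc_fit.model_type != "delay_coupled":
        raise ValueError("expected (linear_fit, delay_coupled_fit)")
    if not (np.isfinite(linear_fit.rmse_ms) and np.isfinite(dc_fit.rmse_ms)):
        raise ValueError("cannot classify a failed fit")
    return bool(dc_fit.rmse_ms < linear_fit.rmse_ms - RMSE_TIE_TOL_MS)


def classify_participant(trial_labels: dict) -> bool:
    """True (coupled) unless some condition has only uncoupled trials.

    ``trial_labels`` maps a condition key (task, cued_rate) to the list of
    retained trial labels in that condition.  Conditions with zero retained
    trials are excluded from the quantifier.  Returns False (uncoupled) iff
    at least one non-empty condition contains no coupled trial.
    """
    any_condition = False
    for labels in trial_labels.values():
        if not labels:
            continue
        any_condition = True
        if not any(labels):
            return False
    if not any_condition:
        raise ValueError("no retained trials for participant")
    return True


def classify_pair(member_labels) -> bool:
    """A pair is coupled only when every member coupled."""
    labels = list(member_labels)
    if len(labels) != 2:
        raise ValueError("a pair has exactly two members")
    return all(labels)


# ---------------------------------------------------------------------------
# canonical tables

EVENT_COLUMNS = ["pair_id", "participant_id", "group", "task", "cued_rate",
                 "cue_period_ms", "trial_index", "repetition", "event_index",
                 "onset_ms", "source"]


def events_frame(trials) -> pd.DataFrame:
    """Long events table: one row per tap or cue onset, 1-based indices."""
    rows = []
    for t in trials:
        common = dict(pair_id=t.pair_id, participant_id=t.participant_id,
                      group=Group(t.group).value, task=t.task,
                      cued_rate=t.cued_rate, cue_period_ms=t.cue_period_ms,
                      trial_index=t.trial_index)
        for i, (onset, rep) in enumerate(zip(t.cue_onsets, t.cue_repetitions)):
            rows.append({**common, "repetition": int(rep), "event_index": i + 1,
                         "onset_ms": float(onset), "source": "cue"})
        for i, (onset, rep) in enumerate(zip(t.tap_onsets, t.tap_repetitions)):
            rows.append({**common, "repetition": int(rep), "event_index": i + 1,
                         "onset_ms": float(onset), "source": "tap"})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def trials_from_events(frame: pd.DataFrame) -> list:
    """Rebuild :class:`TrialRecord` objects from the long events table."""
    trials = []
    keys = ["pair_id", "participant_id", "task", "cued_rate", "trial_index"]
    for _, sub in frame.groupby(keys, sort=True):
        cues = sub[sub["source"] == "cue"].sort_values("event_index")
        taps = sub[sub["source"] == "tap"].sort_values("event_index")
        first = sub.iloc[0]
        trials.append(TrialRecord(
            pair_id=first["pair_id"], participant_id=first["participant_id"],
            group=Group(first["group"]), task=first["task"],
            cued_rate=first["cued_rate"],
            cue_period_ms=float(first["cue_period_ms"]),
            trial_index=int(first["trial_index"]),
            cue_onsets=cues["onset_ms"].to_numpy(),
            tap_onsets=taps["onset_ms"].to_numpy(),
            tap_repetitions=taps["repetition"].to_numpy(dtype=int),
            cue_repetitions=cues["repetition"].to_numpy(dtype=int)))
    return trials


def fits_frame(fits: dict) -> pd.DataFrame:
    """Tidy fits table: one row per trial x model (x stage)."""
    rows = []
    for (key, model_type, stage), fit in fits.items():
        pair_id, participant_id, task, cued_rate, trial_index = key
        rows.append({
            "pair_id": pair_id, "participant_id": participant_id,
            "task": task, "cued_rate": cued_rate, "trial_index": trial_index,
            "model": model_type, "stage": stage,
            "kappa": fit.params.kappa, "omega2_ms": fit.params.omega2_ms,
            "omega_diff_ms": fit.params.omega_diff_ms,
            "tau_ms": fit.params.tau_ms,
            "weighted_sse": fit.weighted_sse, "rmse_ms": fit.rmse_ms,
            "boundary_hit": fit.any_boundary_hit,
            "n_restarts": fit.n_restarts,
            "best_restart": fit.best_restart_index, "seed": fit.seed,
            "failed": fit.failed,
        })
    return pd.DataFrame(rows)


def labels_from_fits_frame(fits: pd.DataFrame) -> pd.DataFrame:
    """Trial/participant/pair coupling labels from a tidy fits table.

    A pure function of the table: re-running on the same input returns the
    same labels.  Uses the final delay-coupled stage present (``fixed_tau``
    if available, else ``free_tau``) against the linear fits.
    """
    dc_stage = "fixed_tau" if (fits["stage"] == "fixed_tau").any() else "free_tau"
    keys = ["pair_id", "participant_id", "task", "cued_rate", "trial_index"]
    dc = fits[(fits["model"] == "delay_coupled") & (fits["stage"] == dc_stage)
              & ~fits["failed"]].set_index(keys)
    lin = fits[(fits["model"] == "linear") & ~fits["failed"]].set_index(keys)
    shared = dc.index.intersection(lin.index)
    rows = []
    for key in shared:
        rmse_dc = float(dc.loc[key, "rmse_ms"])
        rmse_lin = float(lin.loc[key, "rmse_ms"])
        rows.append(dict(zip(keys, key),
                         coupled=bool(rmse_dc < rmse_lin - RMSE_TIE_TOL_MS),
                         rmse_dc=rmse_dc, rmse_linear=rmse_lin))
    labels = pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)
    # participant rule: uncoupled iff some non-empty condition is all-uncoupled
    part = {}
    for pid, sub in labels.groupby("participant_id"):
        conds = {cond: list(g["coupled"])
                 for cond, g in sub.groupby(["task", "cued_rate"])}
        part[pid] = classify_participant(conds)
    labels["participant_coupled"] = labels["participant_id"].map(part)
    pair = {}
    for pair_id, sub in labels.groupby("pair_id"):
        members = sorted(sub["participant_id"].unique())
        if len(members) == 2:
            pair[pair_id] = classify_pair([part[m] for m in members])
    labels["pair_coupled"] = labels["pair_id"].map(pair)
    return labels


def condition_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Cell means by Group x Task x Cued Rate over retained trials.

    Expects the per-trial results table of the pipeline (mean asynchrony,
    variability indices, fitted parameters, retention flags); parameter means
    exclude boundary-hit fits.
    """
    rows = []
    retained = results[results["retained"]]
    cells = [(g, t, c) for g in (Group.MUSICIAN, Group.NONMUSICIAN)
             for t in (Task.SOLO, Task.JOINT)
             for c in (CuedRate.SELF, CuedRate.PARTNER)]
    for g, t, c in cells:
        sub = retained[(retained["group"] == g.value)
                       & (retained["task"] == t.value)
                       & (retained["cued_rate"] == c.value)]
        par = sub[~sub["boundary_hit"]]
        rows.append({
            "group": g.value, "task": t.value, "cued_rate": c.value,
            "n_trials": len(sub),
            "mean_asynchrony_ms": sub["mean_asynchrony_ms"].mean(),
            "cv_iti": sub["cv_iti"].mean(),
            "sd_asynchrony_ms": sub["sd_asynchrony_ms"].mean(),
            "mean_kappa": par["kappa"].mean(),
            "mean_omega_diff_ms": par["omega_diff_ms"].mean(),
        })
    return pd.DataFrame(rows)


def _median_mad(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def ratings_summary(ratings: pd.DataFrame, pair_labels: dict) -> pd.DataFrame:
    """Median (and MAD) of the social-interaction ratings by coupling class.

    ``pair_labels`` maps pair_id to the fitted pair-level coupling label.
    """
    ratings = ratings.copy()
    ratings["pair_coupled"] = ratings["pair_id"].map(pair_labels)
    rows = []
    questions = [c for c in ("pleasantness", "relationship", "synchronization")
                 if c in ratings.columns]
    for question in questions:
        row = {"question": question}
        for label, name in ((True, "coupled"), (False, "uncoupled")):
            vals = ratings.loc[ratings["pair_coupled"] == label, question]
            if len(vals):
                med, mad = _median_mad(vals.to_numpy(dtype=float))
            else:
                med, mad = float("nan"), float("nan")
            row[f"{name}_median"] = med
            row[f"{name}_mad"] = mad
            row[f"{name}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
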