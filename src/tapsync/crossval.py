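"""Train/Test splitting by repetition pairing, test scoring, surrogate baseline.

Each synchronization trial's four tapped repetitions are collapsed into two
8-position series — the {1,3} average and the {2,4} average (pairing first
with third and second with fourth cancels serial-position effects) — one of
which is assigned to Train and the other to Test, balanced across each
participant's trials.  Models are fit to the Train series only; goodness of
fit on Test is the Pearson correlation between predicted and observed
asynchronies (Fisher z-transformed) plus plain RMSE, with parameters frozen.

As a chance baseline, each trial's Train-fit predictions are also scored
against condition-matched *surrogate* series: the same task, cued rate, trial
number and repetition set, taken from one partner in each of the *other*
pairs.  A model that captures individual synchronization dynamics should fit
its own tapper's Test data better than other people's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import AsynchronySeries, TrialRecord
from .estimators import FitResult
from .preprocess import average_repetitions
from .simulate import SimConfig, simulate_delay_coupled, simulate_linear

__all__ = [
    "TRAIN_REP_SETS",
    "CVRecord",
    "split_train_test",
    "assign_balanced_splits",
    "predict_series",
    "fisher_z",
    "evaluate_on_test",
    "build_surrogates",
    "score_surrogates",
]

#: the two repetition pairings; one becomes Train, the other Test
TRAIN_REP_SETS = ((1, 3), (2, 4))

#: correlations are clipped to +/- (1 - 1e-12) before the z-transform
R_CLIP = 1.0 - 1e-12


@dataclass
class CVRecord:
    trial_key: tuple
    model_type: str
    assignment: tuple  # repetition set used for Train
    train_fit: FitResult
    rmse_train: float
    r_test: float
    z_test: float
    rmse_test: float
    r_surrogate: float = float("nan")
    z_surrogate: float = float("nan")
    rmse_surrogate: float = float("nan")
    n_surrogates: int = 0


def split_train_test(trial: TrialRecord, rng: np.random.Generator | None = None,
                     train_reps: tuple | None = None):
    """Average repetitions {1,3} and {2,4}; one is Train, the other Test.

    ``train_reps`` fixes the assignment (used by :func:`assign_balanced_splits`
    to balance assignments within a participant); otherwise it is drawn from
    ``rng``.  Returns ``(train_series, test_series, train_reps)``.
    """
    if train_reps is None:
        if rng is None:
            raise ValueError("either rng or train_reps is required")
        train_reps = TRAIN_REP_SETS[int(rng.integers(2))]
    train_reps = tuple(train_reps)
    if train_reps not in TRAIN_REP_SETS:
        raise ValueError(f"train_reps must be one of {TRAIN_REP_SETS}")
    test_reps = TRAIN_REP_SETS[1 - TRAIN_REP_SETS.index(train_reps)]
    return (average_repetitions(trial, train_reps),
            average_repetitions(trial, test_reps), train_reps)


def assign_balanced_splits(trials, rng: np.random.Generator) -> dict:
    """Per-participant balanced Train assignments: half {1,3}, half {2,4}.

    Returns ``{trial.key: train_reps}``; with an odd trial count the extra
    trial's assignment is random.
    """
    by_participant: dict = {}
    for t in trials:
        by_participant.setdefault(t.participant_id, []).append(t)
    out = {}
    for pid in sorted(by_participant):
        group = by_participant[pid]
        n = len(group)
        labels = np.array([0, 1] * (n // 2) + ([int(rng.integers(2))] if n % 2 else []))
        rng.shuffle(labels)
        for t, lab in zip(group, labels):
            out[t.key] = TRAIN_REP_SETS[lab]
    return out


def predict_series(fit: FitResult, n_events: int = 8,
                   step_ms: float = 1.0) -> np.ndarray:
    """Regenerate a model's predicted asynchronies from fitted parameters."""
    cfg = SimConfig(step_ms=step_ms, n_events=n_events)
    if fit.model_type == "linear":
        return simulate_linear(fit.params, cfg).asynchronies_ms
    return simulate_delay_coupled(fit.params, cfg).asynchronies_ms


def fisher_z(r: float) -> float:
    """Variance-stabilizing ``atanh`` with clipping so perfect fits stay finite."""
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def _score(predicted: np.ndarray, observed: AsynchronySeries):
    """(r, z, rmse) of frozen predictions against an observed series."""
    keep = ~observed.missing_mask & np.isfinite(predicted)
    obs = observed.values[keep]
    pred = predicted[keep]
    if obs.size < 3 or np.std(obs) == 0 or np.std(pred) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, obs).statistic)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2))) if obs.size else float("nan")
    z = fisher_z(r) if np.isfinite(r) else float("nan")
    return r, z, rmse


def evaluate_on_test(train_fit: FitResult, test_series: AsynchronySeries,
                     step_ms: float = 1.0):
    """Score a Train-fit model on held-out data without refitting.

    Returns ``(r, z, rmse)``; ``r`` and ``z`` are NaN when either series has
    zero variance over the shared positions (correlation undefined).
    """
    pred = predict_series(train_fit, n_events=test_series.n_positions,
                          step_ms=step_ms)
    return _score(pred, test_series)


def build_surrogates(trials, target: TrialRecord, test_reps,
                     rng: np.random.Generator):
    """Condition-matched surrogate Test series from every other pair.

    For each pair other than the target's, take the trial of one partner
    (seeded random choice when both match) with the same task, cued rate and
    trial number, averaged over the *same* repetition set as the target's
    Test data.  Pairs with no matching trial are skipped.
    """
    test_reps = tuple(test_reps)
    by_pair: dict = {}
    for t in trials:
        if (t.pair_id != target.pair_id and t.task == target.task
                and t.cued_rate == target.cued_rate
                and t.trial_index == target.trial_index):
            by_pair.setdefault(t.pair_id, []).append(t)
    out = []
    for pair_id in sorted(by_pair):
        candidates = sorted(by_pair[pair_id], key=lambda t: t.participant_id)
        pick = candidates[int(rng.integers(len(candidates)))] \
            if len(candidates) > 1 else candidates[0]
        out.append(average_repetitions(pick, test_reps))
    return out


def score_surrogates(train_fit: FitResult, surrogates,
                     step_ms: float = 1.0, average_in: str = "z"):
    """Mean surrogate fit quality: averaged correlation and mean RMSE.

    Correlations are averaged in z-space by default (consistent with the
    z-transformed analysis); ``average_in="r"`` averages the raw
    correlations instead and z-transforms the mean.
    """
    if average_in not in ("z", "r"):
        raise ValueError("average_in must be 'z' or 'r'")
    if not surrogates:
        return float("nan"), float("nan"), float("nan"), 0
    rs, zs, rmses = [], [], []
    for s in surrogates:
        r, z, rmse = evaluate_on_test(train_fit, s, step_ms=step_ms)
        if np.isfinite(z):
            rs.append(r)
            zs.append(z)
        if np.isfinite(rmse):
            rmses.append(rmse)
    if not zs:
        r_mean, z_mean = float("nan"), float("nan")
    elif average_in == "z":
        z_mean = float(np.mean(zs))
        r_mean = float(np.tanh(z_mean))
    else:
        r_mean = float(np.mean(rs))
        z_mean = fisher_z(r_mean)
    rmse_mean = float(np.mean(rmses)) if rmses else float("nan")
    return r_mean, z_mean, rmse_mean, len(zs)
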