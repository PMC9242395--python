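"""From raw tap/cue onset streams to asynchrony series and variability indices.

Preprocessing steps:

* spontaneous production rate (SPR): mean and CV of the intertap intervals in
  the middle two (most stable) melody repetitions of an uncued trial;
* nearest-neighbor matching of taps to cued beats;
* signed asynchronies, ``tap_onset - cue_onset`` (negative = anticipation);
* per-position averaging of asynchronies across a chosen set of tapped
  repetitions, yielding the 8-position series the oscillator models are fit to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MELODY_LENGTH, REPS_TAPPED, AsynchronySeries, TrialRecord, VariabilityIndices

__all__ = [
    "SPREstimate",
    "compute_spr",
    "match_taps",
    "compute_asynchronies",
    "repetition_asynchronies",
    "average_repetitions",
    "variability_indices",
    "MAX_MASKED_POSITIONS",
]

#: series with more masked positions than this are excluded from model fitting
MAX_MASKED_POSITIONS = 2


@dataclass
class SPREstimate:
    mean_iti_ms: float
    cv_iti: float
    n_itis: int
    flagged: bool = False


def compute_spr(trial: TrialRecord, melody_length: int = MELODY_LENGTH) -> SPREstimate:
    """Spontaneous production rate from the middle two repetitions of an uncued trial.

    Uses the intertap intervals whose *earlier* tap lies in complete
    repetitions 2 or 3 of the four full repetitions; the interval spanning the
    boundary into repetition 4 is excluded, so a standard trial contributes
    ``2 * melody_length - 1`` intervals.  Trials with fewer than 2 usable
    intervals are flagged.
    """
    taps = trial.tap_onsets
    reps = trial.tap_repetitions
    if taps.size < 2:
        return SPREstimate(float("nan"), float("nan"), 0, flagged=True)
    itis = np.diff(taps)
    earlier_rep = reps[:-1]
    later_rep = reps[1:]
    keep = np.isin(earlier_rep, (2, 3)) & (later_rep <= 3)
    itis = itis[keep]
    if itis.size < 2:
        return SPREstimate(float("nan"), float("nan"), int(itis.size), flagged=True)
    mean = float(np.mean(itis))
    cv = float(np.std(itis, ddof=1) / mean)
    return SPREstimate(mean, cv, int(itis.size))


def match_taps(taps: np.ndarray, cues: np.ndarray) -> np.ndarray:
    """Nearest-neighbor matching of taps to cued beats.

    Each tap is assigned to its nearest cue (an exact tie goes to the earlier
    cue); each cue retains at most one tap — when several taps share a nearest
    cue the closer tap wins (tie: the earlier tap) and the others are dropped.

    Returns an integer array of length ``len(cues)`` holding the matched tap
    index per cue, or -1 for cues with no tap.
    """
    taps = np.asarray(taps, dtype=float)
    cues = np.asarray(cues, dtype=float)
    assignment = np.full(cues.size, -1, dtype=int)
    if taps.size == 0 or cues.size == 0:
        return assignment
    # nearest cue per tap; searchsorted gives the insertion point
    right = np.searchsorted(cues, taps)
    left = np.clip(right - 1, 0, cues.size - 1)
    right = np.clip(right, 0, cues.size - 1)
    d_left = np.abs(taps - cues[left])
    d_right = np.abs(taps - cues[right])
    nearest = np.where(d_left <= d_right, left, right)  # tie -> earlier cue
    dist = np.minimum(d_left, d_right)
    for tap_idx in np.argsort(taps, kind="stable"):
        cue_idx = nearest[tap_idx]
        cur = assignment[cue_idx]
        if cur == -1 or dist[tap_idx] < dist[cur]:
            assignment[cue_idx] = tap_idx
    return assignment


def compute_asynchronies(taps: np.ndarray, cues: np.ndarray,
                         assignment: np.ndarray | None = None) -> np.ndarray:
    """Signed asynchrony per cue, ``tap - cue`` in ms; NaN for unmatched cues."""
    taps = np.asarray(taps, dtype=float)
    cues = np.asarray(cues, dtype=float)
    if assignment is None:
        assignment = match_taps(taps, cues)
    out = np.full(cues.size, np.nan)
    matched = assignment >= 0
    out[matched] = taps[assignment[matched]] - cues[matched]
    return out


def repetition_asynchronies(trial: TrialRecord,
                            melody_length: int = MELODY_LENGTH,
                            n_reps: int = REPS_TAPPED) -> np.ndarray:
    """Per-repetition, per-position signed asynchronies of a synchronization trial.

    Taps are matched trial-wide against the full cue stream (a drifting tap
    may land nearest a waiting-block cue, in which case its melody position is
    unobserved).  Returns an ``(n_reps, melody_length)`` array with NaN at
    positions without a matched tap.
    """
    assignment = match_taps(trial.tap_onsets, trial.cue_onsets)
    asynch = compute_asynchronies(trial.tap_onsets, trial.cue_onsets, assignment)
    out = np.full((n_reps, melody_length), np.nan)
    for rep in range(1, n_reps + 1):
        cue_idx = np.flatnonzero(trial.cue_repetitions == rep)
        for pos, ci in enumerate(cue_idx[:melody_length]):
            out[rep - 1, pos] = asynch[ci]
    return out


def average_repetitions(trial: TrialRecord, subset=(1, 2, 3, 4),
                        melody_length: int = MELODY_LENGTH) -> AsynchronySeries:
    """Per-position mean asynchrony over a subset of tapped repetitions.

    Missing positions are excluded from the mean; a position missing in every
    contributing repetition stays masked.
    """
    subset = sorted(set(int(r) for r in subset))
    if not subset or min(subset) < 1 or max(subset) > REPS_TAPPED:
        raise ValueError("subset must be a non-empty subset of {1..4}")
    per_rep = repetition_asynchronies(trial, melody_length=melody_length)
    rows = per_rep[[r - 1 for r in subset], :]
    present = np.isfinite(rows)
    n = present.sum(axis=0)
    values = np.where(n > 0, np.nansum(np.where(present, rows, 0.0), axis=0)
                      / np.maximum(n, 1), np.nan)
    return AsynchronySeries(values=values, missing_mask=~np.isfinite(values),
                            n_reps_averaged=len(subset))


def variability_indices(trial: TrialRecord) -> VariabilityIndices:
    """Mean/CV of ITIs and SD of signed asynchronies for a synchronization trial.

    ITIs are taken within tapped repetitions only (turn-taking gaps between
    repetitions are not intertap intervals).
    """
    itis = []
    for rep in range(1, REPS_TAPPED + 1):
        taps = trial.taps_in_repetition(rep)
        if taps.size >= 2:
            itis.append(np.diff(taps))
    itis = np.concatenate(itis) if itis else np.empty(0)
    asynch = compute_asynchronies(trial.tap_onsets, trial.cue_onsets)
    asynch = asynch[np.isfinite(asynch)]
    if itis.size < 2 or asynch.size < 2:
        return VariabilityIndices(float("nan"), float("nan"), float("nan"), flagged=True)
    mean_iti = float(np.mean(itis))
    return VariabilityIndices(
        mean_iti_ms=mean_iti,
        cv_iti=float(np.std(itis, ddof=1) / mean_iti),
        sd_asynchrony_ms=float(np.std(asynch, ddof=1)),
    )
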