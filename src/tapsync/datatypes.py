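"""Core containers shared across the tapping-synchronization pipeline.

Conventions used throughout the package:

* All onsets and intervals are in milliseconds from the start of a trial.
* An *asynchrony* is signed, ``tap_onset - cue_onset``; negative values mean
  the tapper anticipated (tapped before) the cue.
* A synchronization trial alternates 8-beat tapping blocks with 8-beat
  waiting blocks (turn-taking); four complete tapped repetitions of the
  8-event melody are produced per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

MELODY_LENGTH = 8
REPS_TAPPED = 4


class Group(str, Enum):
    MUSICIAN = "musician"
    NONMUSICIAN = "nonmusician"


class Task(str, Enum):
    SOLO = "Solo"
    JOINT = "Joint"


class CuedRate(str, Enum):
    SELF = "Self"
    PARTNER = "Partner"


@dataclass
class AsynchronySeries:
    """Signed asynchronies (ms) at melody positions 1..n, averaged over repetitions.

    ``values[k-1]`` is the mean asynchrony at serial position ``k``; positions
    with no observed tap in any contributing repetition are masked.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    n_reps_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must have identical shape")
        if np.any(~np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite asynchrony at an unmasked position")

    @classmethod
    def from_values(cls, values, n_reps_averaged: int = 1) -> "AsynchronySeries":
        values = np.asarray(values, dtype=float)
        return cls(values=values, missing_mask=~np.isfinite(values),
                   n_reps_averaged=n_reps_averaged)

    @property
    def n_positions(self) -> int:
        return self.values.size

    @property
    def positions(self) -> np.ndarray:
        """1-based serial positions."""
        return np.arange(1, self.values.size + 1)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


@dataclass
class TrialRecord:
    """One trial's cue and tap onset streams plus condition metadata.

    For synchronization trials ``tap_repetitions`` gives the 1-based tapped
    repetition (turn) of each tap and ``cue_repetitions`` gives, for each cue,
    the tapped repetition whose block it belongs to (0 for waiting blocks).
    SPR (uncued) trials have an empty cue stream and ``tap_repetitions``
    numbering melody repetitions 1..5 (the fifth being the trailing half).
    """

    pair_id: str
    participant_id: str
    group: Group
    task: str  # Task value, or "SPR" for uncued trials
    cued_rate: str  # CuedRate value, or "Uncued" for SPR trials
    cue_period_ms: float
    trial_index: int
    cue_onsets: np.ndarray
    tap_onsets: np.ndarray
    tap_repetitions: np.ndarray
    cue_repetitions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.cue_onsets = np.asarray(self.cue_onsets, dtype=float)
        self.tap_onsets = np.asarray(self.tap_onsets, dtype=float)
        self.tap_repetitions = np.asarray(self.tap_repetitions, dtype=int)
        self.cue_repetitions = np.asarray(self.cue_repetitions, dtype=int)
        for name, stream in (("cue_onsets", self.cue_onsets), ("tap_onsets", self.tap_onsets)):
            if stream.size and (np.any(stream < 0) or np.any(np.diff(stream) <= 0)):
                raise ValueError(f"{name} must be non-negative and strictly increasing")
        if self.tap_onsets.size != self.tap_repetitions.size:
            raise ValueError("one repetition index required per tap")

    @property
    def key(self) -> tuple:
        return (self.pair_id, self.participant_id, self.task, self.cued_rate,
                self.trial_index)

    @property
    def is_synchronization(self) -> bool:
        return self.task in (Task.SOLO.value, Task.JOINT.value)

    def taps_in_repetition(self, rep: int) -> np.ndarray:
        return self.tap_onsets[self.tap_repetitions == rep]

    def cues_in_repetition(self, rep: int) -> np.ndarray:
        return self.cue_onsets[self.cue_repetitions == rep]


@dataclass
class VariabilityIndices:
    """Within-trial variability: mean ITI, CV of ITI, SD of signed asynchrony."""

    mean_iti_ms: float
    cv_iti: float
    sd_asynchrony_ms: float
    flagged: bool = False


@dataclass
class CouplingLabel:
    """Coupled/uncoupled status with the RMSE evidence it was based on."""

    trial_coupled: bool
    rmse_delay_coupled: float
    rmse_linear: float
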