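"""Synthetic turn-taking tapping experiments with known ground-truth dynamics.

The generator emulates the structure of a dyadic synchronization study:
12 pairs (24 participants, musicians paired with musicians and nonmusicians
with nonmusicians), each participant contributing 3 uncued spontaneous-rate
trials and 3 trials x 2 cued rates (own vs. partner's spontaneous rate) x
2 tasks (Solo, Joint) of turn-taking synchronization — 288 synchronization
trials in the default design.  Each synchronization trial alternates 8 cued
beats of tapping with 8 cued beats of waiting, four tapped repetitions in
total.

Taps of a *coupled* participant are produced by forward simulation of the
delay-coupled oscillator (re-initialized at each turn onset: every turn is a
fresh perturbation); taps of an *uncoupled* participant drift at the
participant's own intrinsic period.  Additive i.i.d. Gaussian motor noise is
applied to every tap onset.  Ground-truth parameters are stored per trial so
downstream parameter-recovery and classification can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    MELODY_LENGTH,
    REPS_TAPPED,
    CuedRate,
    Group,
    Task,
    TrialRecord,
)
from .simulate import OscParams, SimConfig, simulate_delay_coupled

__all__ = [
    "ParticipantProfile",
    "PairProfile",
    "ExperimentDesign",
    "Experiment",
    "sample_participant",
    "generate_spr_trial",
    "generate_sync_trial",
    "generate_experiment",
]

RATING_QUESTIONS = ("pleasantness", "relationship", "synchronization")
#: rating centers per coupling class, from the reported medians per question
_RATING_CENTERS = {True: (6.0, 5.0, 6.0), False: (5.0, 3.5, 5.0)}

#: a coupled tapper raises coupling as needed to keep the steady-state
#: asynchrony magnitude near this bound (coupling strength must grow with the
#: intrinsic-rate difference for synchrony to be maintained at all)
STEADY_ASYNC_CAP_MS = 150.0
#: ceiling on the raised coupling, kept inside the fitting bounds
KAPPA_SYNC_MAX = 45.0


def effective_drift_period(profile: "ParticipantProfile",
                           cue_period_ms: float) -> float:
    """Per-trial drift period of an uncoupled tapper.

    Capped at twice the cue period: a tapper taking 8-beat turns cannot
    drift a whole turn past their window, so production compresses toward
    the cue when it is far faster than the spontaneous rate.
    """
    return float(min(profile.spr_ms, 2.0 * cue_period_ms))


def effective_kappa(profile: "ParticipantProfile", cue_period_ms: float) -> float:
    """Per-trial ground-truth coupling of a coupled tapper.

    The baseline coupling is raised when tapping at a cue far from the
    tapper's own rate, so that the steady-state asynchrony magnitude stays
    near ``STEADY_ASYNC_CAP_MS`` (capped at ``KAPPA_SYNC_MAX``); rate
    differences demand stronger coupling, which also reproduces the positive
    coupling/rate-difference association seen in fitted parameters.
    """
    if not profile.coupled:
        return 0.0
    wd = abs(profile.spr_ms - cue_period_ms)
    needed = 20.0 * cue_period_ms * wd / (STEADY_ASYNC_CAP_MS * profile.spr_ms)
    return float(min(KAPPA_SYNC_MAX, max(profile.true_params.kappa, needed)))


@dataclass
class ParticipantProfile:
    participant_id: str
    group: Group
    spr_ms: float
    spr_cv: float
    true_params: OscParams
    motor_noise_sd_ms: float
    coupled: bool

    def __post_init__(self) -> None:
        if self.spr_ms <= 0:
            raise ValueError("spr_ms must be positive")
        if self.spr_cv < 0 or self.motor_noise_sd_ms < 0:
            raise ValueError("variability parameters must be non-negative")


@dataclass
class PairProfile:
    pair_id: str
    members: tuple[ParticipantProfile, ParticipantProfile]
    ratings: dict = field(default_factory=dict)  # participant_id -> (p, r, s)

    def __post_init__(self) -> None:
        if self.members[0].group != self.members[1].group:
            raise ValueError("pair members must share a group")

    @property
    def spr_difference_ms(self) -> float:
        return abs(self.members[0].spr_ms - self.members[1].spr_ms)

    @property
    def coupled(self) -> bool:
        return all(m.coupled for m in self.members)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and generator settings; the defaults reproduce the study design.

    Distributional choices (the study reports only summary values):

    * SPR uniform on ``spr_range_ms`` (only the observed range is known);
    * CV of ITI normal per group (``*_cv``: mean, SD), floored at 0.005;
    * coupling strength ``kappa`` normal per group, clipped to
      ``kappa_clip``; time delay fixed at ``true_tau_ms`` for every tapper;
    * a participant is uncoupled (kappa = 0, pure drift) with probability
      ``p_uncoupled`` (7 of 24 participants in the study);
    * additive Gaussian motor noise on tap onsets, SD per group.
    """

    n_pairs: int = 12
    trials_per_condition: int = 3
    n_spr_trials: int = 3
    melody_length: int = MELODY_LENGTH
    reps_tapped: int = REPS_TAPPED
    seed: int = 0
    spr_range_ms: tuple[float, float] = (305.0, 838.0)
    musician_cv: tuple[float, float] = (0.034, 0.009)
    nonmusician_cv: tuple[float, float] = (0.060, 0.029)
    musician_kappa: tuple[float, float] = (5.3, 2.5)
    nonmusician_kappa: tuple[float, float] = (2.2, 1.2)
    kappa_clip: tuple[float, float] = (0.5, 15.0)
    true_tau_ms: float = 10.15
    p_uncoupled: float = 7.0 / 24.0
    musician_motor_noise_sd_ms: float = 10.0
    nonmusician_motor_noise_sd_ms: float = 20.0
    joint_extra_noise_sd_ms: float = 0.0
    step_ms: float = 1.0

    @property
    def n_participants(self) -> int:
        return 2 * self.n_pairs

    @property
    def sync_trials_per_participant(self) -> int:
        return 2 * 2 * self.trials_per_condition

    @property
    def n_sync_trials(self) -> int:
        return self.sync_trials_per_participant * self.n_participants


@dataclass
class Experiment:
    design: ExperimentDesign
    pairs: list
    trials: list

    @property
    def participants(self) -> list:
        return [m for p in self.pairs for m in p.members]

    @property
    def sync_trials(self) -> list:
        return [t for t in self.trials if t.is_synchronization]

    @property
    def spr_trials(self) -> list:
        return [t for t in self.trials if not t.is_synchronization]

    def ground_truth_frame(self) -> pd.DataFrame:
        """One row per synchronization trial: the generating parameters."""
        profiles = {m.participant_id: m for m in self.participants}
        rows = []
        for t in self.sync_trials:
            p = profiles[t.participant_id]
            rows.append({
                "pair_id": t.pair_id, "participant_id": t.participant_id,
                "task": t.task, "cued_rate": t.cued_rate,
                "trial_index": t.trial_index,
                "cue_period_ms": t.cue_period_ms,
                "true_kappa": effective_kappa(p, t.cue_period_ms),
                "true_omega_diff_ms": (p.spr_ms - t.cue_period_ms if p.coupled
                                       else effective_drift_period(p, t.cue_period_ms)
                                       - t.cue_period_ms),
                "true_tau_ms": p.true_params.tau_ms if p.coupled else 0.0,
                "coupled": p.coupled,
                "motor_noise_sd_ms": p.motor_noise_sd_ms,
            })
        return pd.DataFrame(rows)

    def ratings_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            for m in pair.members:
                vals = pair.ratings[m.participant_id]
                rows.append({"pair_id": pair.pair_id,
                             "participant_id": m.participant_id,
                             "pair_coupled_truth": pair.coupled,
                             **dict(zip(RATING_QUESTIONS, vals))})
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_participant(group: Group, rng: np.random.Generator,
                       design: ExperimentDesign = ExperimentDesign(),
                       participant_id: str = "P1") -> ParticipantProfile:
    """Draw one tapper profile: SPR, variability, regime and true dynamics."""
    group = Group(group)
    spr = float(rng.uniform(*design.spr_range_ms))
    if group is Group.MUSICIAN:
        cv_mean, cv_sd = design.musician_cv
        kap_mean, kap_sd = design.musician_kappa
        noise = design.musician_motor_noise_sd_ms
    else:
        cv_mean, cv_sd = design.nonmusician_cv
        kap_mean, kap_sd = design.nonmusician_kappa
        noise = design.nonmusician_motor_noise_sd_ms
    cv = _truncated_normal(rng, cv_mean, cv_sd, 0.005)
    coupled = bool(rng.random() >= design.p_uncoupled)
    kappa = _truncated_normal(rng, kap_mean, kap_sd, *design.kappa_clip)
    params = OscParams(omega1_ms=spr, omega2_ms=spr,
                       kappa=kappa if coupled else 0.0,
                       tau_ms=design.true_tau_ms if coupled else 0.0)
    return ParticipantProfile(participant_id=participant_id, group=group,
                              spr_ms=spr, spr_cv=cv, true_params=params,
                              motor_noise_sd_ms=noise, coupled=coupled)


def generate_spr_trial(profile: ParticipantProfile, rng: np.random.Generator,
                       design: ExperimentDesign = ExperimentDesign(),
                       trial_index: int = 1, pair_id: str = "pair1") -> TrialRecord:
    """Uncued tapping: 4 1/2 melody repetitions at the spontaneous rate.

    Intertap intervals are i.i.d. normal with mean ``spr_ms`` and SD
    ``spr_cv * spr_ms`` (floored at 1 ms); with zero variability every ITI is
    exactly the spontaneous period.
    """
    n_taps = int(design.reps_tapped * design.melody_length
                 + design.melody_length // 2)
    sd = profile.spr_cv * profile.spr_ms
    if sd > 0:
        itis = np.maximum(rng.normal(profile.spr_ms, sd, n_taps - 1), 1.0)
    else:
        itis = np.full(n_taps - 1, profile.spr_ms)
    taps = np.concatenate([[0.0], np.cumsum(itis)])
    reps = 1 + np.arange(n_taps) // design.melody_length
    return TrialRecord(pair_id=pair_id, participant_id=profile.participant_id,
                       group=profile.group, task="SPR", cued_rate="Uncued",
                       cue_period_ms=float("nan"), trial_index=trial_index,
                       cue_onsets=np.empty(0), tap_onsets=taps,
                       tap_repetitions=reps)


def generate_sync_trial(profile: ParticipantProfile, cue_period_ms: float,
                        design: ExperimentDesign, task: Task,
                        rng: np.random.Generator, cued_rate: CuedRate = CuedRate.SELF,
                        trial_index: int = 1, pair_id: str = "pair1") -> TrialRecord:
    """One turn-taking synchronization trial.

    The metronome runs continuously; the participant taps during blocks
    1, 3, 5, 7 of eight 8-beat blocks (waiting in between).  At each turn
    onset the driven oscillator is re-initialized phase-aligned with the cue
    (asynchrony 0 at the virtual event one beat before the block's first
    cue); tap onsets then follow the ground-truth dynamics plus motor noise.
    """
    if cue_period_ms <= 0:
        raise ValueError("cue_period_ms must be positive")
    ml = design.melody_length
    n_blocks = 2 * design.reps_tapped
    # one-period lead-in keeps the earliest (possibly early) tap positive
    cues = cue_period_ms * (1.0 + np.arange(n_blocks * ml))
    cue_reps = np.zeros(cues.size, dtype=int)
    noise_sd = profile.motor_noise_sd_ms
    if task is Task.JOINT:
        noise_sd = float(np.hypot(noise_sd, design.joint_extra_noise_sd_ms))
    if profile.coupled:
        params = OscParams(omega1_ms=cue_period_ms, omega2_ms=profile.spr_ms,
                           kappa=effective_kappa(profile, cue_period_ms),
                           tau_ms=profile.true_params.tau_ms)
        asynch = simulate_delay_coupled(
            params, SimConfig(step_ms=design.step_ms, n_events=ml)).asynchronies_ms
    else:
        drift = effective_drift_period(profile, cue_period_ms) - cue_period_ms
        asynch = np.arange(1, ml + 1) * drift
    taps, reps = [], []
    for rep in range(1, design.reps_tapped + 1):
        block = 2 * (rep - 1)
        cue_reps[block * ml:(block + 1) * ml] = rep
        block_cues = cues[block * ml:(block + 1) * ml]
        onsets = block_cues + asynch
        if noise_sd > 0:
            onsets = onsets + rng.normal(0.0, noise_sd, ml)
        taps.append(np.sort(onsets))
        reps.append(np.full(ml, rep))
    return TrialRecord(pair_id=pair_id, participant_id=profile.participant_id,
                       group=profile.group, task=task.value,
                       cued_rate=CuedRate(cued_rate).value,
                       cue_period_ms=float(cue_period_ms),
                       trial_index=trial_index, cue_onsets=cues,
                       tap_onsets=np.concatenate(taps),
                       tap_repetitions=np.concatenate(reps).astype(int),
                       cue_repetitions=cue_reps)


def _draw_ratings(coupled_pair: bool, rng: np.random.Generator) -> tuple[int, int, int]:
    centers = _RATING_CENTERS[coupled_pair]
    vals = np.clip(np.round(rng.normal(centers, 0.8)), 1, 7)
    return tuple(int(v) for v in vals)


def generate_experiment(design: ExperimentDesign = ExperimentDesign()) -> Experiment:
    """Generate the full dataset: pairs, SPR trials, Solo and Joint trials, ratings.

    Deterministic given the design (including its seed): the same design
    yields a byte-identical dataset after serialization.
    """
    rng = np.random.default_rng(design.seed)
    pairs = []
    trials = []
    for pair_idx in range(design.n_pairs):
        group = Group.MUSICIAN if pair_idx < design.n_pairs // 2 else Group.NONMUSICIAN
        pair_id = f"pair{pair_idx + 1:02d}"
        members = tuple(
            sample_participant(group, rng, design,
                               participant_id=f"{pair_id}_{suffix}")
            for suffix in ("A", "B"))
        pair = PairProfile(pair_id=pair_id, members=members)
        for m in pair.members:
            pair.ratings[m.participant_id] = _draw_ratings(pair.coupled, rng)
        pairs.append(pair)
        for m_idx, member in enumerate(members):
            partner = members[1 - m_idx]
            for t in range(1, design.n_spr_trials + 1):
                trials.append(generate_spr_trial(member, rng, design,
                                                 trial_index=t, pair_id=pair_id))
            for task in (Task.SOLO, Task.JOINT):
                for cued_rate in (CuedRate.SELF, CuedRate.PARTNER):
                    cue = member.spr_ms if cued_rate is CuedRate.SELF else partner.spr_ms
                    for t in range(1, design.trials_per_condition + 1):
                        trials.append(generate_sync_trial(
                            member, cue, design, task, rng,
                            cued_rate=cued_rate, trial_index=t,
                            pair_id=pair_id))
    return Experiment(design=design, pairs=pairs, trials=trials)
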