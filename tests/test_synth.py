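"""Synthetic-experiment generator: structure, determinism, ground-truth dynamics."""

import numpy as np
import pytest

from tapsync.datatypes import CuedRate, Group, Task
from tapsync.preprocess import average_repetitions, compute_spr
from tapsync.report import events_frame
from tapsync.simulate import OscParams, simulate_delay_coupled
from tapsync.synth import (
    ExperimentDesign,
    effective_kappa,
    generate_experiment,
    generate_spr_trial,
    generate_sync_trial,
    sample_participant,
)


class TestSampleParticipant:
    def test_spr_within_range_and_deterministic(self):
        for seed in range(5):
            p1 = sample_participant(Group.MUSICIAN, np.random.default_rng(seed))
            p2 = sample_participant(Group.MUSICIAN, np.random.default_rng(seed))
            assert 305 <= p1.spr_ms <= 838
            assert (p1.spr_ms, p1.spr_cv, p1.coupled) == (
                p2.spr_ms, p2.spr_cv, p2.coupled)

    def test_musicians_less_variable_on_average(self):
        rng = np.random.default_rng(0)
        design = ExperimentDesign()
        cvs = {g: np.mean([sample_participant(g, rng, design).spr_cv
                           for _ in range(2000)])
               for g in (Group.MUSICIAN, Group.NONMUSICIAN)}
        assert cvs[Group.MUSICIAN] < cvs[Group.NONMUSICIAN]

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            sample_participant("violinist", np.random.default_rng(0))


class TestSprTrial:
    def test_zero_noise_itis_exact(self, rng):
        p = sample_participant(Group.MUSICIAN, rng)
        p.spr_cv = 0.0
        trial = generate_spr_trial(p, rng)
        assert np.allclose(np.diff(trial.tap_onsets), p.spr_ms)

    def test_tap_count_four_and_a_half_melodies(self, rng):
        p = sample_participant(Group.MUSICIAN, rng)
        trial = generate_spr_trial(p, rng)
        assert trial.tap_onsets.size == 36
        assert trial.tap_repetitions.max() == 5

    def test_spr_recovered_exactly_without_noise(self, rng):
        p = sample_participant(Group.NONMUSICIAN, rng)
        p.spr_cv = 0.0
        est = compute_spr(generate_spr_trial(p, rng))
        assert est.mean_iti_ms == pytest.approx(p.spr_ms, abs=1e-9)


class TestSyncTrial:
    def _noiseless(self, rng, coupled):
        design = ExperimentDesign(musician_motor_noise_sd_ms=0.0)
        while True:
            p = sample_participant(Group.MUSICIAN, rng, design)
            if p.coupled == coupled:
                p.motor_noise_sd_ms = 0.0
                return p, design

    def test_cues_periodic_and_taps_in_tapping_blocks(self, rng):
        p, design = self._noiseless(rng, True)
        trial = generate_sync_trial(p, 500.0, design, Task.SOLO, rng)
        assert np.allclose(np.diff(trial.cue_onsets), 500.0)
        assert trial.cue_onsets.size == 64
        assert trial.tap_onsets.size == 32
        assert set(trial.tap_repetitions) == {1, 2, 3, 4}
        # no taps during waiting blocks: every tap near its own block
        for rep in range(1, 5):
            taps = trial.taps_in_repetition(rep)
            cues = trial.cues_in_repetition(rep)
            assert taps.size == 8 and cues.size == 8

    def test_coupled_matches_forward_simulation_exactly(self, rng):
        p, design = self._noiseless(rng, True)
        trial = generate_sync_trial(p, 520.0, design, Task.SOLO, rng)
        expected = simulate_delay_coupled(
            OscParams(520.0, p.spr_ms, effective_kappa(p, 520.0),
                      p.true_params.tau_ms)).asynchronies_ms
        series = average_repetitions(trial)
        assert np.allclose(series.values, expected, atol=1e-9)

    def test_uncoupled_drift_is_linear_in_position(self, rng):
        p, design = self._noiseless(rng, False)
        p.spr_ms = 550.0
        trial = generate_sync_trial(p, 500.0, design, Task.SOLO, rng)
        per_rep_async = trial.taps_in_repetition(1) - trial.cues_in_repetition(1)
        assert np.allclose(per_rep_async, np.arange(1, 9) * 50.0)

    def test_nonpositive_cue_period_rejected(self, rng):
        p, design = self._noiseless(rng, True)
        with pytest.raises(ValueError):
            generate_sync_trial(p, 0.0, design, Task.SOLO, rng)


class TestExperiment:
    def test_design_counts(self, small_experiment):
        exp = small_experiment  # 2 pairs
        assert len(exp.participants) == 4
        assert len(exp.sync_trials) == 4 * 12
        per = {}
        for t in exp.sync_trials:
            per[t.participant_id] = per.get(t.participant_id, 0) + 1
        assert set(per.values()) == {12}

    def test_default_design_is_full_study_layout(self):
        d = ExperimentDesign()
        assert d.n_sync_trials == 288
        assert d.sync_trials_per_participant == 12

    def test_joint_trials_use_both_members_sprs(self, small_experiment):
        for pair in small_experiment.pairs:
            sprs = {round(m.spr_ms, 6) for m in pair.members}
            joint_periods = {round(t.cue_period_ms, 6)
                             for t in small_experiment.sync_trials
                             if t.pair_id == pair.pair_id
                             and t.task == Task.JOINT.value}
            assert joint_periods == sprs

    def test_byte_identical_regeneration(self):
        d = ExperimentDesign(n_pairs=2, seed=31)
        a = events_frame(generate_experiment(d).trials).to_csv(index=False)
        b = events_frame(generate_experiment(d).trials).to_csv(index=False)
        assert a == b

    def test_ground_truth_sidecar_covers_all_sync_trials(self, small_experiment):
        gt = small_experiment.ground_truth_frame()
        assert len(gt) == len(small_experiment.sync_trials)
        assert set(gt.columns) >= {"true_kappa", "true_omega_diff_ms",
                                   "true_tau_ms", "coupled"}
        # self-cued trials have zero rate difference by construction
        self_cued = gt[gt["cued_rate"] == CuedRate.SELF.value]
        assert np.allclose(self_cued["true_omega_diff_ms"], 0.0)

    def test_uncoupled_pairs_rate_lower(self):
        # medians of the rating generator by ground-truth coupling class
        rng_design = ExperimentDesign(n_pairs=40, seed=3)
        exp = generate_experiment(rng_design)
        r = exp.ratings_frame()
        coupled = r[r["pair_coupled_truth"]]
        uncoupled = r[~r["pair_coupled_truth"]]
        assert len(coupled) and len(uncoupled)
        for q in ("pleasantness", "relationship", "synchronization"):
            assert coupled[q].median() >= uncoupled[q].median()
        assert (coupled["relationship"].median()
                > uncoupled["relationship"].median())


class TestEffectiveKappa:
    def test_rises_with_rate_difference(self, rng):
        p = sample_participant(Group.MUSICIAN, rng)
        while not p.coupled:
            p = sample_participant(Group.MUSICIAN, rng)
        kappas = [effective_kappa(p, p.spr_ms + d) for d in (0, 100, 200, 300)]
        assert all(a <= b for a, b in zip(kappas, kappas[1:]))
        assert kappas[0] == p.true_params.kappa

    def test_zero_for_uncoupled(self, rng):
        p = sample_participant(Group.MUSICIAN, rng)
        p.coupled = False
        assert effective_kappa(p, 400.0) == 0.0
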