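"""Preprocessing: SPR estimation, tap-cue matching, asynchronies, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tapsync.datatypes import Group, TrialRecord
from tapsync.preprocess import (
    average_repetitions,
    compute_asynchronies,
    compute_spr,
    match_taps,
    repetition_asynchronies,
    variability_indices,
)


def make_spr_trial(itis):
    taps = np.concatenate([[0.0], np.cumsum(itis)])
    reps = 1 + np.arange(taps.size) // 8
    return TrialRecord("p1", "p1_A", Group.MUSICIAN, "SPR", "None", float("nan"),
                       1, np.empty(0), taps, reps)


def make_sync_trial(asynch_by_rep, period=500.0, noise=None):
    """Trial with 8 blocks of 8 cues; taps = cue + given asynchrony."""
    cues = period * (1 + np.arange(64))
    cue_reps = np.zeros(64, dtype=int)
    taps, reps = [], []
    for rep in range(1, 5):
        block = 2 * (rep - 1)
        cue_reps[block * 8:(block + 1) * 8] = rep
        onsets = cues[block * 8:(block + 1) * 8] + np.asarray(asynch_by_rep[rep - 1])
        taps.append(onsets)
        reps.append(np.full(8, rep))
    return TrialRecord("p1", "p1_A", Group.MUSICIAN, "Solo", "Self", period, 1,
                       cues, np.concatenate(taps), np.concatenate(reps),
                       cue_repetitions=cue_reps)


class TestComputeSPR:
    def test_periodic_taps_exact(self):
        est = compute_spr(make_spr_trial(np.full(35, 500.0)))
        assert est.mean_iti_ms == pytest.approx(500.0)
        assert est.cv_iti == pytest.approx(0.0, abs=1e-12)
        assert est.n_itis == 15  # reps 2-3 minus the rep3->4 boundary

    def test_jittered_matches_enumeration_oracle(self, rng):
        itis = rng.normal(480, 25, 35)
        est = compute_spr(make_spr_trial(itis))
        # oracle: enumerate ITIs whose earlier tap is in reps 2-3 (taps 8..23
        # 0-based), dropping the one spanning into rep 4
        window = itis[8:23]
        assert est.mean_iti_ms == pytest.approx(np.mean(window))
        assert est.cv_iti == pytest.approx(np.std(window, ddof=1) / np.mean(window))

    def test_deterministic(self, rng):
        trial = make_spr_trial(rng.normal(480, 25, 35))
        a, b = compute_spr(trial), compute_spr(trial)
        assert (a.mean_iti_ms, a.cv_iti) == (b.mean_iti_ms, b.cv_iti)

    def test_too_few_taps_flagged(self):
        est = compute_spr(make_spr_trial(np.full(3, 500.0)))
        assert est.flagged


def brute_force_match(taps, cues):
    """Oracle: nearest cue per tap (tie -> earlier), closest tap keeps a cue."""
    assignment = np.full(len(cues), -1, dtype=int)
    for ti, tap in enumerate(taps):
        dists = np.abs(np.asarray(cues) - tap)
        ci = int(np.argmin(dists))  # argmin takes the first (earlier) on ties
        cur = assignment[ci]
        if cur == -1 or dists[ci] < abs(taps[cur] - cues[ci]):
            assignment[ci] = ti
    return assignment


class TestMatchTaps:
    def test_identity_matching(self):
        cues = np.array([500.0, 1000, 1500])
        assert np.array_equal(match_taps(cues, cues), [0, 1, 2])
        assert np.allclose(compute_asynchronies(cues, cues), 0.0)

    def test_forced_nearest(self):
        assignment = match_taps([1040.0], [500.0, 1000.0, 1500.0])
        assert np.array_equal(assignment, [-1, 0, -1])

    def test_tie_goes_to_earlier_cue(self):
        assignment = match_taps([750.0], [500.0, 1000.0])
        assert np.array_equal(assignment, [0, -1])

    def test_extra_tap_dropped_keeping_closer(self):
        # both taps nearest to cue 1000; 990 is closer so 940 is dropped
        assignment = match_taps([940.0, 990.0], [1000.0])
        assert np.array_equal(assignment, [1])

    def test_empty_inputs(self):
        assert match_taps([], [1.0, 2.0]).tolist() == [-1, -1]
        assert match_taps([1.0], []).size == 0

    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=15, unique=True))
    def test_matches_brute_force(self, taps):
        taps = np.sort(np.asarray(taps))
        if np.any(np.diff(taps) <= 0):
            return
        cues = np.arange(250.0, 4800.0, 500.0)
        assert np.array_equal(match_taps(taps, cues),
                              brute_force_match(taps, cues))


class TestAsynchronies:
    def test_sign_convention(self):
        out = compute_asynchronies([990.0], [1000.0])
        assert out[0] == pytest.approx(-10.0)

    def test_batch_equals_elementwise_subtraction(self, rng):
        cues = np.arange(500.0, 4500.0, 500.0)
        taps = cues + rng.normal(0, 30, cues.size)
        taps = np.sort(taps)
        out = compute_asynchronies(taps, cues)
        finite = np.isfinite(out)
        a = match_taps(taps, cues)
        for ci in np.flatnonzero(finite):
            assert out[ci] == pytest.approx(taps[a[ci]] - cues[ci])


class TestAverageRepetitions:
    def test_identical_repetitions_idempotent(self):
        a = np.array([-5.0, 3, 8, 11, 12, 13, 12, 14])
        trial = make_sync_trial([a, a, a, a])
        s = average_repetitions(trial)
        assert np.allclose(s.values, a)
        assert s.n_reps_averaged == 4

    def test_subsets_partition_all_reps(self):
        reps = [np.arange(8.0) * (i + 1) for i in range(4)]
        trial = make_sync_trial(reps)
        s13 = average_repetitions(trial, (1, 3))
        s24 = average_repetitions(trial, (2, 4))
        s_all = average_repetitions(trial)
        assert np.allclose((s13.values + s24.values) / 2, s_all.values)

    def test_hand_computed_means(self):
        reps = [np.full(8, 4.0), np.full(8, 8.0), np.full(8, 16.0),
                np.full(8, 32.0)]
        trial = make_sync_trial(reps)
        assert np.allclose(average_repetitions(trial, (1, 2)).values, 6.0)
        assert np.allclose(average_repetitions(trial, (3, 4)).values, 24.0)

    def test_missing_position_masked(self):
        # rep-2 tap at position 4 drifts into the waiting block before its cue
        reps = [np.zeros(8), np.zeros(8), np.zeros(8), np.zeros(8)]
        trial = make_sync_trial(reps)
        per_rep = repetition_asynchronies(trial)
        assert np.all(np.isfinite(per_rep))

    def test_invalid_subset_rejected(self):
        trial = make_sync_trial([np.zeros(8)] * 4)
        with pytest.raises(ValueError):
            average_repetitions(trial, (0, 5))


class TestVariabilityIndices:
    def test_constant_iti_zero_cv(self):
        trial = make_sync_trial([np.zeros(8)] * 4)
        vi = variability_indices(trial)
        assert vi.cv_iti == pytest.approx(0.0, abs=1e-12)
        assert vi.mean_iti_ms == pytest.approx(500.0)

    def test_constant_asynchrony_zero_sd(self):
        trial = make_sync_trial([np.full(8, -15.0)] * 4)
        vi = variability_indices(trial)
        assert vi.sd_asynchrony_ms == pytest.approx(0.0, abs=1e-12)

    def test_toy_case_matches_direct_formula(self, rng):
        reps = [rng.normal(0, 12, 8) for _ in range(4)]
        trial = make_sync_trial(reps)
        vi = variability_indices(trial)
        itis = np.concatenate([np.diff(trial.taps_in_repetition(r))
                               for r in range(1, 5)])
        assert vi.mean_iti_ms == pytest.approx(np.mean(itis))
        assert vi.cv_iti == pytest.approx(np.std(itis, ddof=1) / np.mean(itis))
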