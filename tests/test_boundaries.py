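"""Within/across-event correlation test and entropy-at-transition test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emodyn.boundaries import (
    boundary_pattern_test,
    entropy_match_test,
    shuffle_event_lengths,
    timepoint_corr,
    within_across_stat,
)
from emodyn.eventseg import HmmConfig, fit
from emodyn.timeline import music_tr_labels


class TestTimepointCorr:
    def test_identical_rows_all_ones(self):
        x = np.tile(np.array([1.0, 2.0, 5.0, -1.0]), (4, 1))
        assert np.allclose(timepoint_corr(x), 1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal((3, 4))
        c = timepoint_corr(x)
        for i in range(3):
            for j in range(3):
                assert c[i, j] == pytest.approx(np.corrcoef(x[i], x[j])[0, 1])

    def test_zero_variance_row_zeroed_with_warning(self, rng):
        x = rng.standard_normal((4, 5))
        x[2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            c = timepoint_corr(x)
        assert np.allclose(c[2], 0.0) and np.allclose(c[:, 2], 0.0)


class TestWithinAcrossStat:
    def test_block_diagonal_gives_one(self):
        lab = np.array([0, 0, 0, 1, 1, 1])
        c = np.zeros((6, 6))
        c[:3, :3] = 1.0
        c[3:, 3:] = 1.0
        assert within_across_stat(c, lab) == pytest.approx(1.0)

    def test_constant_matrix_gives_zero(self):
        c = np.full((6, 6), 0.4)
        assert within_across_stat(c, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.0)

    def test_matches_enumeration_on_toy(self, rng):
        """Hand enumeration: 6 TRs, 2 events of 3; 6 within pairs, 9 across."""
        x = rng.standard_normal((6, 5))
        c = timepoint_corr(x)
        lab = np.array([0, 0, 0, 1, 1, 1])
        within = [c[i, j] for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]]
        across = [c[i, j] for i in range(3) for j in range(3, 6)]
        assert within_across_stat(c, lab) == pytest.approx(
            np.mean(within) - np.mean(across)
        )

    def test_unlabeled_trs_excluded(self, rng):
        x = rng.standard_normal((8, 5))
        c = timepoint_corr(x)
        lab = np.array([0, 0, 0, -1, -1, 1, 1, 1])
        sub = np.array([0, 1, 2, 5, 6, 7])
        assert within_across_stat(c, lab) == pytest.approx(
            within_across_stat(c[np.ix_(sub, sub)], lab[sub])
        )

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError):
            within_across_stat(np.eye(4), np.zeros(4, dtype=int))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_feature_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((12, 6))
        lab = np.repeat([0, 1, 2], 4)
        a = within_across_stat(timepoint_corr(x), lab)
        b = within_across_stat(timepoint_corr(x[:, rng.permutation(6)]), lab)
        assert a == pytest.approx(b)


class TestShuffleEventLengths:
    def test_single_event_identical(self):
        perms = shuffle_event_lengths([5], 10, seed=0)
        assert all(np.array_equal(p, np.zeros(5, dtype=int)) for p in perms)

    def test_length_multiset_preserved(self):
        lengths = np.array([3, 5, 2, 4])
        for p in shuffle_event_lengths(lengths, 20, seed=1):
            _, counts = np.unique(p, return_counts=True)
            assert sorted(counts) == sorted(lengths)

    def test_three_events_at_most_six_orderings(self):
        seen = {tuple(p) for p in shuffle_event_lengths([2, 3, 4], 200, seed=2)}
        assert len(seen) <= 6


class TestBoundaryPatternTest:
    def test_detects_structure_at_high_snr(self, small_cohort, timelines):
        g = small_cohort.group_mean("A", 1)
        res = boundary_pattern_test(
            g, music_tr_labels(timelines[("A", 1)]), n_perm=200, seed=0
        )
        assert res.p <= 0.05
        assert res.observed > 0

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            boundary_pattern_test(rng.standard_normal((20, 4)),
                                  np.repeat([0, 1], 10), n_perm=0)

    def test_p_never_zero(self, small_cohort, timelines):
        g = small_cohort.group_mean("A", 1)
        res = boundary_pattern_test(
            g, music_tr_labels(timelines[("A", 1)]), n_perm=50, seed=1
        )
        assert 0 < res.p <= 1


class TestEntropyMatchTest:
    def test_peaks_at_transitions_give_large_z(self):
        T = 120
        trs = np.array([17, 42, 81, 99])  # irregular gaps
        trace = np.zeros(T)
        trace[trs] = 1.0
        res = entropy_match_test(trace, trs, n_perm=300, seed=0)
        assert res.z > 3
        assert res.p <= 0.01

    def test_constant_trace_z_zero(self):
        res = entropy_match_test(np.full(80, 0.3), np.array([10, 40]), n_perm=100, seed=0)
        assert res.z == 0.0

    def test_seed_reproducible(self, rng):
        trace = rng.uniform(size=100)
        trs = np.array([10, 30, 60])
        a = entropy_match_test(trace, trs, n_perm=100, seed=5)
        b = entropy_match_test(trace, trs, n_perm=100, seed=5)
        assert a.p == b.p and np.array_equal(a.null_values, b.null_values)

    def test_empty_transition_list_rejected(self):
        with pytest.raises(ValueError):
            entropy_match_test(np.zeros(50), np.array([]), n_perm=10)

    def test_fitted_cohort_entropy_matches_boundaries(self, small_cohort):
        """On simulated data the posterior is maximally uncertain at the
        true switch TRs."""
        g = small_cohort.group_mean("A", 1)
        seg = fit(g, HmmConfig(n_events=16))
        res = entropy_match_test(
            seg, small_cohort.boundaries[("A", 1)], n_perm=300, seed=0,
            window_tr=1,
        )
        assert res.p <= 0.05
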