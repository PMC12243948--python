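"""Properties of the synthetic-cohort generator."""

import numpy as np
import pytest

from emodyn.eventseg import HmmConfig, find_boundaries, fit
from emodyn.power import match_fraction
from emodyn.synth import (
    SimSpec,
    make_event_patterns,
    make_surface_graph,
    simulate_button_presses,
    simulate_cohort,
    simulate_ratings,
    simulate_subject,
)
from emodyn.timeline import catalogue_events


class TestEventPatterns:
    def test_deterministic(self):
        keys = [("calm", i) for i in range(32)]
        a = make_event_patterns(80, keys, seed=3)
        b = make_event_patterns(80, keys, seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_event_patterns(80, keys, seed=4))

    def test_low_pairwise_correlation(self):
        keys = [("calm", i) for i in range(32)]
        p = make_event_patterns(80, keys, seed=0)
        r = np.corrcoef(p)
        off = np.abs(r[np.triu_indices(32, 1)])
        assert off.mean() < 0.25

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            make_event_patterns(1, [("calm", 1)], seed=0)


def _patterns_for(spec, timelines):
    keys = sorted(catalogue_events(timelines).keys())
    p = make_event_patterns(spec.n_features, keys, seed=spec.seed)
    return {k: p[i] for i, k in enumerate(keys)}


class TestSimulateSubject:
    def test_noiseless_limit_within_event_stability(self, timelines, tlA1):
        spec = SimSpec(n_subjects=2, n_units=40, n_features=20, snr=1e6,
                       context_shift=0.0, timing_delay_tr=0, hrf_smooth_tr=0.0,
                       seed=0)
        sd = simulate_subject(spec, tlA1, _patterns_for(spec, timelines), seed=1)
        x = sd.data
        # within event 2 (TRs 46..80) patterns are identical up to z-scoring
        assert np.corrcoef(x[50], x[70])[0, 1] > 0.99
        # across the adjacent boundary they are near the (random) pattern corr
        assert abs(np.corrcoef(x[80], x[95])[0, 1]) < 0.6

    def test_pure_noise_uncorrelated_with_truth(self, timelines, tlA1):
        spec = SimSpec(n_subjects=2, n_units=40, n_features=20, snr=0.0, seed=0)
        pats = _patterns_for(spec, timelines)
        sd = simulate_subject(spec, tlA1, pats, seed=1)
        proj = sd.data  # no signal at all
        rs = []
        for i, e in enumerate(tlA1.events):
            from emodyn.timeline import music_tr_labels

            trs = np.where(music_tr_labels(tlA1) == i)[0]
            mean_vox = proj[trs].mean(axis=0)
            rs.append(np.corrcoef(mean_vox[:20], pats[e.key])[0, 1])
        assert np.mean(np.abs(rs)) < 0.2

    def test_ar1_autocorrelation_recovered(self, timelines, tlA1):
        spec = SimSpec(n_subjects=2, n_units=200, n_features=20, snr=0.0,
                       ar_coef=0.4, drift_amplitude=0.0, white_frac=0.05, seed=0)
        sd = simulate_subject(spec, tlA1, _patterns_for(spec, timelines), seed=2)
        x = sd.data
        lag1 = np.mean(np.sum(x[1:] * x[:-1], axis=0) / np.sum(x * x, axis=0))
        # expected (1 - white_frac) * ar = 0.38
        assert abs(lag1 - 0.4) < 0.05

    def test_negative_snr_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(snr=-0.1)


class TestCohort:
    def test_versions_alternate(self, small_cohort):
        assert small_cohort.versions.tolist() == [1, 2, 1, 2, 1, 2, 1, 2]

    def test_deterministic(self, timelines):
        spec = SimSpec(n_subjects=4, n_units=30, n_features=10, seed=11)
        a = simulate_cohort(spec, timelines)
        b = simulate_cohort(spec, timelines)
        assert np.array_equal(a.subjects[2]["B"].data, b.subjects[2]["B"].data)
        assert np.array_equal(a.align_latent, b.align_latent)

    def test_alignment_run_shared_signal(self, timelines):
        spec = SimSpec(n_subjects=6, n_units=30, n_features=10, snr=5.0,
                       shared_voxel_map=True, seed=2, align_trs=200)
        ds = simulate_cohort(spec, timelines)
        mats = [s["align"].data for s in ds.subjects]
        rs = [
            np.corrcoef(mats[i].ravel(), mats[j].ravel())[0, 1]
            for i in range(6) for j in range(i + 1, 6)
        ]
        assert np.mean(rs) > 0.9

    def test_ground_truth_carried(self, small_cohort):
        for key, b in small_cohort.boundaries.items():
            assert len(b) == 15
            assert (np.diff(b) > 0).all()
        assert small_cohort.patterns.shape == (32, 20)

    def test_snr_monotone_boundary_recovery(self, timelines):
        """Downstream recovery accuracy is non-decreasing in snr."""
        tls = {k: v for k, v in timelines.items() if k[0] == "A"}
        accs = []
        for snr in (0.1, 0.5, 2.0):
            spec = SimSpec(n_subjects=6, n_units=40, n_features=20, snr=snr,
                           shared_voxel_map=True, seed=5)
            ds = simulate_cohort(spec, tls)
            seg = fit(ds.group_mean("A", 1), HmmConfig(n_events=16))
            accs.append(
                match_fraction(ds.boundaries[("A", 1)], find_boundaries(seg))
            )
        slack = 1 / 15  # one boundary of Monte-Carlo jitter
        assert accs[1] >= accs[0] - slack
        assert accs[2] >= accs[1] - slack
        assert accs[2] > accs[0]


class TestBehaviorGenerators:
    def test_rater_count_and_columns(self, tlA1):
        df = simulate_button_presses(tlA1, n_raters=36, seed=0)
        assert df["rater"].nunique() == 36
        assert set(df.columns) == {"rater", "label", "action", "time_s"}

    def test_zero_latency_zero_spurious_presses_at_onsets(self, tlA1):
        df = simulate_button_presses(
            tlA1, latency_mean_s=1e-6, latency_context_penalty_s=0.0,
            press_prob=1.0, spurious_rate_per_min=0.0, n_raters=3, seed=0,
        )
        ons = df[df.action == "on"]
        onsets = np.array([e.onset_s for e in tlA1.events])
        d = np.min(np.abs(ons.time_s.to_numpy()[:, None] - onsets[None, :]), axis=1)
        assert d.max() < 0.01

    def test_ratings_shape_and_range(self, timelines):
        df = simulate_ratings(timelines, n_subjects=5, context_effect=0.0, seed=0)
        assert len(df) == 5 * 32
        for emo in ("calm", "happy", "sad", "anxious", "nostalgic"):
            assert df[emo].between(1, 7).all()


class TestSurfaceGraph:
    def test_grid_properties(self):
        import networkx as nx

        g = make_surface_graph(10, 10)
        assert g.number_of_nodes() == 100
        assert nx.is_connected(g)
        degrees = dict(g.degree)
        assert max(degrees.values()) <= 8
        assert degrees[0] == 3  # corner under 4-neighbour + diagonals

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_surface_graph(1, 1)
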