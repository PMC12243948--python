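"""Acoustic feature extraction and behavioral validation statistics."""

import numpy as np
import pandas as pd
import pytest

from emodyn import behavior as beh
from emodyn.acoustics import (
    FEATURE_COLUMNS,
    extract_acoustic_features,
    feature_rating_correlations,
)
from emodyn.synth import simulate_button_presses, simulate_ratings

SR = 2000  # low working rate keeps the 15-minute piece tractable in tests
FRAME, HOP = 1024, 512


def _full_piece_wave(tl, kind="tone", seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(tl.total_music_s * SR)) / SR
    if kind == "tone":
        return 0.3 * np.sin(2 * np.pi * 220 * t)
    return 0.3 * rng.standard_normal(len(t))


@pytest.fixture(scope="module")
def tone_feats(tlA1):
    y = _full_piece_wave(tlA1, "tone")
    return extract_acoustic_features(y, SR, tlA1, FRAME, HOP, target_sr=SR)


class TestAcousticFeatures:
    def test_constant_tone_rms_sd_near_zero(self, tone_feats):
        assert (tone_feats["rms_sd"] < 1e-3).all()

    def test_amplitude_doubling_doubles_rms(self, tlA1, tone_feats):
        y = 2 * _full_piece_wave(tlA1, "tone")
        feats2 = extract_acoustic_features(y, SR, tlA1, FRAME, HOP, target_sr=SR)
        assert np.allclose(
            feats2["rms_mean"], 2 * tone_feats["rms_mean"], rtol=1e-6
        )

    def test_noise_has_wider_spectrum_than_tone(self, tlA1, tone_feats):
        y = _full_piece_wave(tlA1, "noise")
        noise_feats = extract_acoustic_features(y, SR, tlA1, FRAME, HOP, target_sr=SR)
        assert (
            noise_feats["spectral_spread"] > tone_feats["spectral_spread"]
        ).all()

    def test_deterministic(self, tlA1, tone_feats):
        y = _full_piece_wave(tlA1, "tone")
        again = extract_acoustic_features(y, SR, tlA1, FRAME, HOP, target_sr=SR)
        pd.testing.assert_frame_equal(tone_feats, again)

    def test_short_event_window_rejected(self, tlA1):
        y = np.zeros(int(30 * SR))  # waveform ends before most events
        with pytest.raises(ValueError, match="shorter than one frame"):
            extract_acoustic_features(y, SR, tlA1, FRAME, HOP, target_sr=SR)


class TestFeatureRatingCorrelations:
    def _tables(self, rng, n=32):
        feats = pd.DataFrame(
            rng.standard_normal((n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        ratings = pd.DataFrame(
            rng.standard_normal((n, 5)),
            columns=["calm", "happy", "sad", "anxious", "nostalgic"],
        )
        return feats, ratings

    def test_copy_gives_unit_correlation(self, rng):
        feats, ratings = self._tables(rng)
        ratings["calm"] = feats["rms_mean"]
        out = feature_rating_correlations(feats, ratings)
        assert out.loc["rms_mean", "calm"] == pytest.approx(1.0)

    def test_schema_rows_and_columns(self, rng):
        feats, ratings = self._tables(rng)
        out = feature_rating_correlations(feats, ratings)
        assert "rms_mean" in out.index and "spectral_novelty" in out.index
        assert list(out.columns) == ["calm", "happy", "sad", "anxious", "nostalgic"]

    def test_independent_columns_weakly_correlated(self, rng):
        feats, ratings = self._tables(rng)
        out = feature_rating_correlations(feats, ratings)
        assert np.abs(out.to_numpy(dtype=float)).mean() < 0.25

    def test_constant_column_zero_with_warning(self, rng):
        feats, ratings = self._tables(rng)
        feats["rms_mean"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = feature_rating_correlations(feats, ratings)
        assert (out.loc["rms_mean"] == 0).all()


class TestPressTransitionTest:
    def test_transition_locked_presses_give_large_z(self, tlA1):
        times = np.array([e.onset_s for e in tlA1.events[1:]])
        rows = [
            (r, "calm", "on", t + 1.0) for r in range(20) for t in times
        ]
        df = pd.DataFrame(rows, columns=["rater", "label", "action", "time_s"])
        res = beh.press_transition_test(df, times, tlA1.total_music_s,
                                        n_perm=300, seed=0)
        assert res.z > 4

    def test_zero_presses(self, tlA1):
        df = pd.DataFrame(columns=["rater", "label", "action", "time_s"])
        times = np.array([e.onset_s for e in tlA1.events[1:]])
        res = beh.press_transition_test(df, times, tlA1.total_music_s,
                                        n_perm=100, seed=0)
        assert res.observed == 0
        assert res.p > 0.9

    def test_oversized_window_rejected(self, tlA1):
        with pytest.raises(ValueError):
            beh.press_transition_test(
                pd.DataFrame(columns=["rater", "label", "action", "time_s"]),
                np.array([100.0]), tlA1.total_music_s, window=(0, 1000.0),
            )


class TestIntendedEmotionTest:
    def test_perfect_raters_give_small_p(self, tlA1):
        rows = []
        for r in range(12):
            for e in tlA1.events:
                rows.append((r, e.emotion.value, "on", e.onset_s + 0.5))
                rows.append((r, e.emotion.value, "off", e.offset_s - 0.5))
        df = pd.DataFrame(rows, columns=["rater", "label", "action", "time_s"])
        out = beh.intended_emotion_test(df, tlA1, n_perm=200, seed=0)
        assert set(out) == {"calm", "happy", "sad", "anxious", "nostalgic"}
        for emo, res in out.items():
            if emo != "nostalgic":  # bookends are hit by any labeling scheme
                assert res.p <= 0.05
            assert res.observed == 12

    def test_generator_counts_near_half_of_raters(self, tlA1):
        df = simulate_button_presses(tlA1, n_raters=36, seed=4)
        out = beh.intended_emotion_test(df, tlA1, n_perm=100, seed=0)
        for res in out.values():
            assert 10 <= res.observed <= 28  # ~half of 36, as in the validation data


class TestTimeToThreshold:
    def test_penalty_recovered(self, timelines):
        presses = {k: simulate_button_presses(tl, seed=11)
                   for k, tl in timelines.items()}
        out = beh.time_to_threshold_contrast(presses, timelines,
                                             n_perm=300, seed=0)
        assert out["positive"].observed == pytest.approx(9.0, abs=3.0)
        assert out["positive"].p <= 0.05
        assert out["negative"].observed == pytest.approx(9.0, abs=3.0)

    def test_zero_penalty_gives_no_contrast(self, timelines):
        presses = {
            k: simulate_button_presses(tl, latency_context_penalty_s=0.0, seed=3)
            for k, tl in timelines.items()
        }
        out = beh.time_to_threshold_contrast(presses, timelines,
                                             n_perm=200, seed=0)
        assert abs(out["positive"].observed) < 3.0

    def test_frac_one_is_last_increment(self, timelines):
        presses = {k: simulate_button_presses(tl, seed=5)
                   for k, tl in timelines.items()}
        full = beh.time_to_threshold_contrast(presses, timelines, frac=1.0,
                                              n_perm=10, seed=0)
        lat = full["latencies"]
        tl = timelines[("A", 1)]
        row = lat[(lat.piece == "A") & (lat.version == 1)].iloc[0]
        e = tl.events[int(row.event_no) - 1]
        on = presses[("A", 1)]
        sel = on[(on.label == e.emotion.value) & (on.action == "on")
                 & (on.time_s >= e.onset_s) & (on.time_s < e.offset_s)]
        last = sel.groupby("rater")["time_s"].min().max()
        assert row.latency_s == pytest.approx(last - e.onset_s)

    def test_bad_frac_rejected(self, timelines):
        with pytest.raises(ValueError):
            beh.time_to_threshold_contrast({}, timelines, frac=0.0)


class TestRatingContext:
    def test_context_effect_detected(self, timelines):
        df = simulate_ratings(timelines, n_subjects=16, context_effect=0.8, seed=2)
        res = beh.rating_context_correlation(df, n_perm=200, seed=0)
        assert res.observed > 0
        assert res.p <= 0.05

    def test_no_effect_gives_small_difference(self, timelines):
        df = simulate_ratings(timelines, n_subjects=16, context_effect=0.0, seed=2)
        res = beh.rating_context_correlation(df, n_perm=200, seed=0)
        assert abs(res.observed) < 0.05

    def test_single_subject_version_rejected(self, timelines):
        df = simulate_ratings(timelines, n_subjects=3, context_effect=0.0, seed=0)
        with pytest.raises(ValueError, match="2 subjects"):
            beh.rating_context_correlation(df, n_perm=10)
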