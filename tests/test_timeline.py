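"""Event-table loading, transition typing, and TR-grid projection."""

import numpy as np
import pandas as pd
import pytest
from importlib import resources

from emodyn.timeline import (
    Emotion,
    TimelineError,
    TransitionClass,
    Valence,
    builtin_timeline,
    catalogue_events,
    classify_transitions,
    load_timeline,
    music_tr_labels,
    to_tr_grid,
    transition_counts,
    write_timeline,
)


class TestLoading:
    def test_published_durations(self, timelines):
        """Durations recomputed from onset/offset match the printed table."""
        assert timelines[("A", 1)].events[1].duration_s == 52  # calm, row 2
        assert timelines[("B", 1)].events[7].duration_s == 27  # happy, row 8
        for tl in timelines.values():
            for e in tl.events:
                assert 27 <= e.duration_s <= 72

    def test_wrong_event_count_rejected(self, tmp_path, tlA1):
        df = tlA1.to_frame().iloc[:15]
        p = tmp_path / "short.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(TimelineError, match="expected 16 events"):
            load_timeline(p, "A", 1)

    def test_unknown_emotion_rejected(self, tmp_path, tlA1):
        df = tlA1.to_frame()
        df.loc[3, "emotion"] = "elated"
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(TimelineError, match="elated"):
            load_timeline(p, "A", 1)

    def test_overlap_rejected_naming_row(self, tmp_path, tlA1):
        df = tlA1.to_frame()
        df.loc[4, "onset"] = 230  # overlaps row 4's offset 240
        p = tmp_path / "overlap.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(TimelineError, match="row 5"):
            load_timeline(p, "A", 1)

    def test_roundtrip_bit_exact(self, tmp_path):
        """write(load(x)) reproduces the bundled TSV byte-for-byte."""
        for piece in ("A", "B"):
            for version in (1, 2):
                tl = builtin_timeline(piece, version)
                out = tmp_path / f"{piece}{version}.tsv"
                write_timeline(tl, out)
                ref = (
                    resources.files("emodyn.data") / f"piece{piece}_v{version}.tsv"
                ).read_text()
                assert out.read_text() == ref


class TestTransitions:
    def test_examples_from_table(self, timelines):
        labels = classify_transitions(timelines[("A", 1)])
        # events 3->4: happy -> sad
        assert labels[2].klass is TransitionClass.DIFFERENT_VALENCE
        # events 4->5: sad -> anxious
        assert labels[3].klass is TransitionClass.SAME_VALENCE
        # events 1->2: nostalgic -> calm
        assert labels[0].klass is TransitionClass.EXCLUDED

    def test_counts_sum_to_15_each_version(self, timelines):
        for tl in timelines.values():
            counts = transition_counts(tl)
            assert sum(counts.values()) == 15
            # table-derived counts (the prose claims 7/7; the table gives 7/6)
            assert counts["same_valence"] == 7
            assert counts["different_valence"] == 6
            assert counts["excluded"] == 2

    def test_valence_mapping(self):
        assert Emotion.CALM.valence is Valence.POSITIVE
        assert Emotion.HAPPY.valence is Valence.POSITIVE
        assert Emotion.SAD.valence is Valence.NEGATIVE
        assert Emotion.ANXIOUS.valence is Valence.NEGATIVE
        assert Emotion.NOSTALGIC.valence is Valence.MIXED


class TestTrGrid:
    def test_full_run_is_607_images(self, tlA1):
        """6 s silence + 896 s music at TR 1.5 + 9 s silence = 607 TRs."""
        assert len(to_tr_grid(tlA1)) == 607

    def test_half_open_coverage(self, tlA1):
        labels = music_tr_labels(tlA1)
        # event 2 (calm) spans [69, 121): TR 46 starts at 69.0, TR 80 at 120.0
        assert labels[45] == -1  # 67.5 s: interlude
        assert labels[46] == 1
        assert labels[80] == 1
        assert labels[81] == -1  # 121.5 s: interlude

    def test_interlude_trs_unlabeled(self, tlA1):
        labels = music_tr_labels(tlA1)
        assert (labels == -1).sum() > 0
        # silence padding in the full grid
        grid = to_tr_grid(tlA1)
        assert (grid[:4] == -1).all() and (grid[-6:] == -1).all()

    def test_lag_shift(self, tlA1):
        g0 = to_tr_grid(tlA1)
        g2 = to_tr_grid(tlA1, lag_trs=2)
        assert (g2[2:] == g0[:-2]).all()
        assert (g2[:2] == -1).all()

    def test_negative_tr_rejected(self, tlA1):
        with pytest.raises(ValueError):
            music_tr_labels(tlA1, tr_s=-1.0)


class TestCatalogue:
    def test_32_unique_events_4_nostalgic(self, timelines):
        cat = catalogue_events(timelines)
        assert len(cat) == 32
        nostalgic = [k for k in cat if k[0] == "nostalgic"]
        assert len(nostalgic) == 4
        for rec in cat.values():
            assert set(rec["versions"]) == {1, 2}

    def test_event_in_both_pieces_rejected(self, timelines):
        tlA = timelines[("A", 1)].to_frame()
        tlB = timelines[("B", 1)].to_frame()
        # move a piece-A exemplar key into piece B
        tlB.loc[1, ["emotion", "emotion_no"]] = ["sad", 1]
        from emodyn.timeline import EventTimeline, MusicEvent, parse_emotion

        events = tuple(
            MusicEvent("B", 1, int(r.event_no), parse_emotion(r.emotion),
                       int(r.emotion_no), float(r.onset), float(r.offset))
            for r in tlB.itertuples()
        )
        bad = EventTimeline("B", 1, events)
        with pytest.raises(TimelineError, match="both pieces"):
            catalogue_events([timelines[("A", 1)], bad])
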