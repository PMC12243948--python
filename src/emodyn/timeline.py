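"""Composer-defined event structure of the two musical pieces.

Each piece is a ~15 min composition divided into 16 emotional events
(calm, happy, sad, anxious at the extremes of the valence axis, plus
dreamy/nostalgic bookends treated as mixed valence).  Every piece exists
in two versions that contain the same events in a different order, so
that the emotional context (the valence of the preceding event) of a
given event differs between versions.  This module loads and validates
those event tables, types the transitions between adjacent events, and
projects the timeline onto the fMRI sampling grid (TR = 1.5 s).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Emotion",
    "Valence",
    "MusicEvent",
    "EventTimeline",
    "TransitionClass",
    "TransitionLabel",
    "load_timeline",
    "write_timeline",
    "builtin_timeline",
    "all_builtin_timelines",
    "classify_transitions",
    "transition_counts",
    "to_tr_grid",
    "music_tr_labels",
    "catalogue_events",
    "TimelineError",
    "TR_S",
    "TOTAL_MUSIC_S",
    "PRE_SILENCE_S",
    "POST_SILENCE_S",
    "N_EVENTS",
]

#: fMRI repetition time of the acquisition this design targets, seconds.
TR_S = 1.5
#: Duration of the musical portion of each run, seconds (597 TRs).
TOTAL_MUSIC_S = 896.0
#: Silence before the music starts / after it ends within a run, seconds.
PRE_SILENCE_S = 6.0
POST_SILENCE_S = 9.0
#: Events per piece version.
N_EVENTS = 16

#: Allowed duration range of a single event, seconds.
DURATION_RANGE_S = (27.0, 72.0)
#: Interludes were composed at 4-12 s; validation allows [0, 15] because one
#: printed gap (Piece A V2, events 3->4) is 13 s.
MAX_GAP_S = 15.0


class TimelineError(ValueError):
    """Raised when an event table violates the design's structure."""


class Valence(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    MIXED = "mixed"


class Emotion(str, enum.Enum):
    CALM = "calm"
    HAPPY = "happy"
    SAD = "sad"
    ANXIOUS = "anxious"
    NOSTALGIC = "nostalgic"

    @property
    def valence(self) -> Valence:
        return _VALENCE[self]


_VALENCE = {
    Emotion.CALM: Valence.POSITIVE,
    Emotion.HAPPY: Valence.POSITIVE,
    Emotion.SAD: Valence.NEGATIVE,
    Emotion.ANXIOUS: Valence.NEGATIVE,
    Emotion.NOSTALGIC: Valence.MIXED,
}

# The published table names categories as e.g. "Joyous/cheerful"; accept
# those spellings as aliases of the canonical labels.
_EMOTION_ALIASES = {
    "calm": Emotion.CALM,
    "calm/relaxing": Emotion.CALM,
    "relaxing": Emotion.CALM,
    "happy": Emotion.HAPPY,
    "joyous": Emotion.HAPPY,
    "joyous/cheerful": Emotion.HAPPY,
    "cheerful": Emotion.HAPPY,
    "sad": Emotion.SAD,
    "sad/depressing": Emotion.SAD,
    "depressing": Emotion.SAD,
    "anxious": Emotion.ANXIOUS,
    "anxious/tense": Emotion.ANXIOUS,
    "tense": Emotion.ANXIOUS,
    "nostalgic": Emotion.NOSTALGIC,
    "dreamy": Emotion.NOSTALGIC,
    "dreamy/nostalgic": Emotion.NOSTALGIC,
}


def parse_emotion(name: str) -> Emotion:
    try:
        return _EMOTION_ALIASES[str(name).strip().lower()]
    except KeyError:
        raise TimelineError(f"unknown emotion label: {name!r}") from None


class TransitionClass(str, enum.Enum):
    SAME_VALENCE = "same_valence"
    DIFFERENT_VALENCE = "different_valence"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class MusicEvent:
    """One composer-defined emotional event within a piece version."""

    piece: str
    version: int
    index: int  # 1-based position within the version
    emotion: Emotion
    exemplar_no: int
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def key(self) -> tuple[str, int]:
        """Identity of the musical material, shared across versions."""
        return (self.emotion.value, self.exemplar_no)

    @property
    def valence(self) -> Valence:
        return self.emotion.valence


@dataclass(frozen=True)
class TransitionLabel:
    from_event: MusicEvent
    to_event: MusicEvent
    klass: TransitionClass


@dataclass(frozen=True)
class EventTimeline:
    """Validated, ordered event list of one piece version."""

    piece: str
    version: int
    events: tuple[MusicEvent, ...]
    total_music_s: float = TOTAL_MUSIC_S

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev) != N_EVENTS:
            raise TimelineError(
                f"{self.piece} v{self.version}: expected {N_EVENTS} events, got {len(ev)}"
            )
        lo, hi = DURATION_RANGE_S
        prev_off = 0.0
        for e in ev:
            row = e.index
            if e.offset_s <= e.onset_s:
                raise TimelineError(f"row {row}: offset must exceed onset")
            if not (lo <= e.duration_s <= hi):
                raise TimelineError(
                    f"row {row}: duration {e.duration_s:g} s outside [{lo:g}, {hi:g}]"
                )
            gap = e.onset_s - prev_off
            if gap < 0:
                raise TimelineError(f"row {row}: overlaps previous event")
            if e.index > 1 and gap > MAX_GAP_S:
                raise TimelineError(f"row {row}: interlude {gap:g} s exceeds {MAX_GAP_S:g} s")
            prev_off = e.offset_s
        if ev[0].emotion is not Emotion.NOSTALGIC or ev[-1].emotion is not Emotion.NOSTALGIC:
            raise TimelineError("first and last events must be nostalgic bookends")
        if ev[-1].offset_s > self.total_music_s:
            raise TimelineError("final offset exceeds total music duration")
        keys = [e.key for e in ev]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise TimelineError(f"duplicate event key within version: {dup}")

    @property
    def keys(self) -> list[tuple[str, int]]:
        return [e.key for e in self.events]

    def event_by_key(self, key: tuple[str, int]) -> MusicEvent:
        for e in self.events:
            if e.key == tuple(key):
                return e
        raise KeyError(f"event {key} not in {self.piece} v{self.version}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_no": [e.index for e in self.events],
                "emotion": [e.emotion.value for e in self.events],
                "emotion_no": [e.exemplar_no for e in self.events],
                "onset": [_as_num(e.onset_s) for e in self.events],
                "offset": [_as_num(e.offset_s) for e in self.events],
            }
        )


def _as_num(x: float):
    return int(x) if float(x).is_integer() else float(x)


def load_timeline(path: str | Path, piece: str, version: int) -> EventTimeline:
    """Read one event table (TSV: event_no, emotion, emotion_no, onset, offset).

    Durations are recomputed from onset/offset; a duration column, if
    present, is ignored.  Structural violations raise :class:`TimelineError`
    naming the offending row.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"event_no", "emotion", "emotion_no", "onset", "offset"}
    missing = required - set(df.columns)
    if missing:
        raise TimelineError(f"{path}: missing columns {sorted(missing)}")
    if len(df) != N_EVENTS:
        raise TimelineError(f"{path}: expected {N_EVENTS} events, got {len(df)}")
    events = tuple(
        MusicEvent(
            piece=piece,
            version=int(version),
            index=int(r.event_no),
            emotion=parse_emotion(r.emotion),
            exemplar_no=int(r.emotion_no),
            onset_s=float(r.onset),
            offset_s=float(r.offset),
        )
        for r in df.itertuples()
    )
    return EventTimeline(piece=piece, version=int(version), events=events)


def write_timeline(tl: EventTimeline, path: str | Path) -> None:
    """Write a timeline back to TSV, preserving integer onsets/offsets."""
    tl.to_frame().to_csv(path, sep="\t", index=False)


def builtin_timeline(piece: str, version: int) -> EventTimeline:
    """Load one of the four bundled event tables (piece 'A'/'B', version 1/2)."""
    piece = piece.upper()
    if piece not in ("A", "B") or version not in (1, 2):
        raise ValueError("piece must be 'A'/'B' and version 1/2")
    ref = resources.files("emodyn.data") / f"piece{piece}_v{version}.tsv"
    with resources.as_file(ref) as p:
        return load_timeline(p, piece, version)


def all_builtin_timelines() -> dict[tuple[str, int], EventTimeline]:
    return {
        (p, v): builtin_timeline(p, v) for p in ("A", "B") for v in (1, 2)
    }


def classify_transitions(tl: EventTimeline) -> list[TransitionLabel]:
    """Label the 15 adjacent event pairs by valence relationship.

    A transition is excluded when either endpoint is nostalgic (mixed
    valence); otherwise same_valence iff both events share a non-mixed
    valence.
    """
    out = []
    for a, b in zip(tl.events[:-1], tl.events[1:]):
        if Valence.MIXED in (a.valence, b.valence):
            klass = TransitionClass.EXCLUDED
        elif a.valence is b.valence:
            klass = TransitionClass.SAME_VALENCE
        else:
            klass = TransitionClass.DIFFERENT_VALENCE
        out.append(TransitionLabel(a, b, klass))
    return out


def transition_counts(tl: EventTimeline) -> dict[str, int]:
    labels = classify_transitions(tl)
    return {
        k.value: sum(1 for t in labels if t.klass is k) for k in TransitionClass
    }


def incoming_transition(tl: EventTimeline, key: tuple[str, int]) -> TransitionLabel:
    """Transition leading into the event identified by ``key``."""
    ev = tl.event_by_key(key)
    if ev.index == 1:
        raise TimelineError(f"event {key} is first in {tl.piece} v{tl.version}; no predecessor")
    return classify_transitions(tl)[ev.index - 2]


def music_tr_count(tr_s: float = TR_S, total_music_s: float = TOTAL_MUSIC_S) -> int:
    return int(np.floor(total_music_s / tr_s))


def music_tr_labels(tl: EventTimeline, tr_s: float = TR_S) -> np.ndarray:
    """Per-TR event labels over the musical portion only (length 597 at 1.5 s).

    TR t covers music time [t*tr_s, (t+1)*tr_s), half-open and 0-based; a TR
    belongs to the event whose [onset, offset) window contains the TR start.
    Interlude TRs get -1 (belong to no event).
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    n = music_tr_count(tr_s, tl.total_music_s)
    labels = np.full(n, -1, dtype=int)
    starts = np.arange(n) * tr_s
    for i, e in enumerate(tl.events):
        labels[(starts >= e.onset_s) & (starts < e.offset_s)] = i
    return labels


def to_tr_grid(
    tl: EventTimeline,
    tr_s: float = TR_S,
    pre_silence_s: float = PRE_SILENCE_S,
    post_silence_s: float = POST_SILENCE_S,
    lag_trs: int = 0,
) -> np.ndarray:
    """Per-TR event labels over the full scanning run (607 TRs by default).

    The run is pre-silence TRs + floor(total_music/tr) music TRs + post
    silence TRs.  Silence and interlude TRs are labeled -1.  ``lag_trs``
    shifts labels later in time by an integer number of TRs to mimic
    hemodynamic delay (default 0: no shift).
    """
    if pre_silence_s < 0 or post_silence_s < 0:
        raise ValueError("silence durations must be nonnegative")
    pre = int(round(pre_silence_s / tr_s))
    post = int(round(post_silence_s / tr_s))
    music = music_tr_labels(tl, tr_s)
    grid = np.concatenate([np.full(pre, -1), music, np.full(post, -1)])
    if lag_trs:
        shifted = np.full_like(grid, -1)
        if lag_trs < len(grid):
            shifted[lag_trs:] = grid[: len(grid) - lag_trs]
        grid = shifted
    return grid


def catalogue_events(
    timelines: Iterable[EventTimeline] | Mapping[tuple[str, int], EventTimeline],
) -> dict[tuple[str, int], dict]:
    """Unique event catalogue across all four piece versions.

    Events are keyed by (emotion, exemplar_no); each must appear in exactly
    the two versions of a single piece.  The full design yields 32 unique
    events, 4 of them nostalgic.
    """
    if isinstance(timelines, Mapping):
        timelines = list(timelines.values())
    cat: dict[tuple[str, int], dict] = {}
    for tl in timelines:
        for e in tl.events:
            rec = cat.setdefault(
                e.key,
                {"emotion": e.emotion.value, "exemplar_no": e.exemplar_no,
                 "piece": e.piece, "versions": {}},
            )
            if rec["piece"] != e.piece:
                raise TimelineError(
                    f"event {e.key} appears in both pieces ({rec['piece']} and {e.piece})"
                )
            if e.version in rec["versions"]:
                raise TimelineError(
                    f"event {e.key} duplicated within {e.piece} v{e.version}"
                )
            rec["versions"][e.version] = {
                "index": e.index,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
            }
    return cat


def catalogue_to_json(cat: Mapping[tuple[str, int], dict], path: str | Path) -> None:
    serial = {f"{emo}:{no}": rec for (emo, no), rec in cat.items()}
    Path(path).write_text(json.dumps(serial, indent=2))
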