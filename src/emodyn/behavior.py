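"""Behavioral validation statistics for the continuous-rating and
retrospective-rating data.

Press logs come from listeners who toggled one of five emotion labels on
and off while hearing a piece; the tests ask whether presses cluster at
composer-defined transitions, whether the selected labels match the
intended emotions, and whether the latency to report an emotion depends
on the valence of the preceding event.  Retrospective ratings are tested
for version (context) dependence via inter-subject rating correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import PermutationResult
from .timeline import (
    Emotion,
    EventTimeline,
    TransitionClass,
    Valence,
    classify_transitions,
)

__all__ = [
    "press_transition_test",
    "intended_emotion_test",
    "time_to_threshold_contrast",
    "rating_context_correlation",
]

#: Default window around a transition in which a press counts as
#: transition-locked, seconds relative to the transition time.
DEFAULT_WINDOW = (-1.5, 5.7)


def _count_raters_in_windows(
    press: pd.DataFrame, starts: np.ndarray, width: float, offset: float
) -> int:
    """Number of raters pressing inside each window, summed over windows."""
    t = press["time_s"].to_numpy()
    raters = press["rater"].to_numpy()
    total = 0
    for s in starts:
        hit = (t >= s + offset) & (t <= s + offset + width)
        total += len(np.unique(raters[hit]))
    return int(total)


def press_transition_test(
    press_logs: pd.DataFrame,
    transition_times: np.ndarray,
    piece_duration_s: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Are raters more likely to press at transitions than elsewhere?

    Observed: the number of raters with an ON/OFF press inside each true
    transition window, summed over transitions.  Null: the same number of
    non-overlapping windows placed uniformly at random within the piece.
    """
    lo, hi = window
    width = hi - lo
    times = np.asarray(transition_times, dtype=float)
    if width <= 0 or width > piece_duration_s:
        raise ValueError("window must be positive and narrower than the piece")
    if len(times) * width > piece_duration_s:
        raise ValueError("transition windows cannot fit in the piece")
    observed = _count_raters_in_windows(press_logs, times, width, lo)
    rng = np.random.default_rng(seed)
    n_win = len(times)
    slack = piece_duration_s - n_win * width
    null = np.empty(n_perm)
    for i in range(n_perm):
        # sorted uniforms + cumulative widths => non-overlapping windows
        starts = np.sort(rng.uniform(0, slack, n_win)) + width * np.arange(n_win)
        null[i] = _count_raters_in_windows(press_logs, starts, width, 0.0)
    return PermutationResult.from_null(observed, null, seed)


def _on_intervals(press_logs: pd.DataFrame, duration_s: float) -> pd.DataFrame:
    """Pair on/off presses into ON intervals per (rater, label).

    A dangling ON closes at the end of the piece; an OFF without a prior
    ON is ignored.
    """
    rows = []
    for (rater, label), grp in press_logs.groupby(["rater", "label"]):
        open_t = None
        for _, r in grp.sort_values("time_s").iterrows():
            if r.action == "on" and open_t is None:
                open_t = r.time_s
            elif r.action == "off" and open_t is not None:
                rows.append((rater, label, open_t, r.time_s))
                open_t = None
        if open_t is not None:
            rows.append((rater, label, open_t, duration_s))
    return pd.DataFrame(rows, columns=["rater", "label", "start", "end"])


def _event_label_counts(
    intervals: pd.DataFrame, spans: list[tuple[float, float]], labels: list[str]
) -> np.ndarray:
    """Per event, number of raters with the given label ON at any point inside."""
    counts = np.zeros(len(spans))
    for i, ((a, b), lab) in enumerate(zip(spans, labels)):
        sel = intervals[
            (intervals["label"] == lab)
            & (intervals["start"] < b)
            & (intervals["end"] > a)
        ]
        counts[i] = sel["rater"].nunique()
    return counts


def intended_emotion_test(
    press_logs: pd.DataFrame,
    tl: EventTimeline,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Did raters select the composer-intended emotion during each event?

    Observed, per emotion category: mean over its events of the number of
    raters whose label was ON at some point during the event.  Null:
    shuffle the emotion labels across the 16 events and recount.
    """
    intervals = _on_intervals(press_logs, tl.total_music_s)
    spans = [(e.onset_s, e.offset_s) for e in tl.events]
    labels = [e.emotion.value for e in tl.events]

    def per_emotion(labs: list[str]) -> dict[str, float]:
        counts = _event_label_counts(intervals, spans, labs)
        return {
            emo.value: float(np.mean([c for c, l in zip(counts, labs) if l == emo.value]))
            for emo in Emotion
            if emo.value in labs
        }

    observed = per_emotion(labels)
    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {emo: [] for emo in observed}
    for _ in range(n_perm):
        shuffled = list(rng.permutation(labels))
        for emo, val in per_emotion(shuffled).items():
            null[emo].append(val)
    return {
        emo: PermutationResult.from_null(observed[emo], np.array(null[emo]), seed)
        for emo in observed
    }


def _event_latencies(
    press_logs: pd.DataFrame, tl: EventTimeline, frac: float
) -> pd.DataFrame:
    """Latency per event until the cumulative count of raters who turned the
    intended emotion ON reaches frac of its maximum."""
    trans = classify_transitions(tl)
    rows = []
    for i, e in enumerate(tl.events):
        if i == 0 or e.valence is Valence.MIXED:
            continue
        klass = trans[i - 1].klass
        if klass is TransitionClass.EXCLUDED:
            continue
        on = press_logs[
            (press_logs["label"] == e.emotion.value)
            & (press_logs["action"] == "on")
            & (press_logs["time_s"] >= e.onset_s)
            & (press_logs["time_s"] < e.offset_s)
        ]
        first = on.groupby("rater")["time_s"].min().sort_values()
        if len(first) == 0:
            warnings.warn(
                f"event {e.index} ({e.emotion.value}): no ON presses; excluded",
                stacklevel=2,
            )
            continue
        need = int(np.ceil(frac * len(first)))
        t_thresh = first.iloc[need - 1]
        rows.append(
            {
                "piece": tl.piece,
                "version": tl.version,
                "event_no": e.index,
                "valence": e.valence.value,
                "incoming": klass.value,
                "latency_s": float(t_thresh - e.onset_s),
            }
        )
    return pd.DataFrame(rows)


def time_to_threshold_contrast(
    press_logs_by_version: dict[tuple[str, int], pd.DataFrame],
    timelines: dict[tuple[str, int], EventTimeline],
    frac: float = 0.9,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Latency to report the intended emotion, by predecessor valence.

    Events from all piece versions are pooled into PP/NP (positive events
    by same/different predecessor valence) and NN/PN (negative events).
    Observed contrasts: mean(NP) - mean(PP) and mean(PN) - mean(NN)
    (different minus same; positive values mean slower onset after a
    valence change).  Null: permute the incoming-class labels within each
    polarity.  First events and nostalgic bookends are excluded.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    lat = pd.concat(
        [
            _event_latencies(press_logs_by_version[k], timelines[k], frac)
            for k in sorted(press_logs_by_version)
        ],
        ignore_index=True,
    )
    rng = np.random.default_rng(seed)
    out: dict = {"latencies": lat}
    for pol in ("positive", "negative"):
        sub = lat[lat["valence"] == pol]
        same = sub.loc[sub["incoming"] == "same_valence", "latency_s"].to_numpy()
        diff = sub.loc[sub["incoming"] == "different_valence", "latency_s"].to_numpy()
        if len(same) == 0 or len(diff) == 0:
            raise ValueError(f"{pol} events: a transition class is empty")
        observed = float(diff.mean() - same.mean())
        pooled = np.concatenate([same, diff])
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[len(same):].mean() - perm[: len(same)].mean()
        out[pol] = PermutationResult.from_null(observed, null, seed)
    return out


_EMO_COLS = [e.value for e in Emotion]


def rating_context_correlation(
    ratings: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Within-version minus across-version inter-subject rating similarity.

    For each unique event, every pair of subjects contributes the Pearson
    correlation of their 5-emotion rating vectors; pairs who heard the
    event in the same version are 'within', others 'across'.  Observed:
    mean within - mean across, pooled over events.  Null: shuffle the
    subjects' version labels.
    """
    subjects = np.sort(ratings["subject"].unique())
    version_of = (
        ratings.drop_duplicates("subject").set_index("subject")["version"]
    )
    versions = version_of.loc[subjects].to_numpy()
    if min((versions == 1).sum(), (versions == 2).sum()) < 2:
        raise ValueError("need at least 2 subjects per version")

    # events x subjects x 5 rating tensor and per-event pairwise correlations
    piv = ratings.pivot_table(
        index=["piece", "emotion", "exemplar_no"],
        columns="subject",
        values=_EMO_COLS,
    )
    n_s = len(subjects)
    corr_sum = np.zeros((n_s, n_s))
    n_events = 0
    for key in piv.index:
        mat = np.stack(
            [piv.loc[key, (c,)].loc[subjects].to_numpy() for c in _EMO_COLS]
        )  # (5, n_subjects)
        if np.isnan(mat).any():
            continue
        corr_sum += np.corrcoef(mat.T)
        n_events += 1
    if n_events == 0:
        raise ValueError("no fully rated events")
    corr = corr_sum / n_events
    iu = np.triu_indices(n_s, 1)

    def stat(v: np.ndarray) -> float:
        same = v[iu[0]] == v[iu[1]]
        return float(corr[iu][same].mean() - corr[iu][~same].mean())

    observed = stat(versions)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(versions)) for _ in range(n_perm)])
    return PermutationResult.from_null(observed, null, seed)
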