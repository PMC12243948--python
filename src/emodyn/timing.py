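"""Does the neural transition into an event come earlier when the
preceding event shares its valence?

For every event that is preceded by a same-valence exemplar in one
version of its piece and a different-valence exemplar in the other, a
2-state HMM is fit to the group-mean feature time series of the
(predecessor + event) window from each version.  The per-TR expected
event index (labels 0/1) summed over the window counts TRs assigned to
the current event, so a higher sum means an earlier transition.  The
same-minus-different difference in sums, averaged over events, converts
to seconds via the TR; significance comes from shuffling which version
counts as the same-valence presentation (sign flips).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import PermutationResult
from .eventseg import HmmConfig, expected_event_index, find_boundaries, fit
from .timeline import (
    EventTimeline,
    TransitionClass,
    classify_transitions,
    music_tr_labels,
)

__all__ = ["paired_event_windows", "transition_sum", "valence_timing_contrast"]


def paired_event_windows(
    tl_v1: EventTimeline,
    tl_v2: EventTimeline,
    event_key: tuple[str, int],
    tr_s: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-length TR windows (predecessor + event) for both versions.

    Interlude TRs are excluded.  The longer predecessor is cropped at its
    start and, where the exemplar's printed duration differs between
    versions, the longer event is cropped at its end, so both windows
    have identical TR counts and the transition neighbourhood is kept
    intact.  Raises for the first event of a piece (no predecessor).
    """
    windows = []
    for tl in (tl_v1, tl_v2):
        ev = tl.event_by_key(event_key)
        if ev.index == 1:
            raise ValueError(f"event {event_key} opens {tl.piece} v{tl.version}: no predecessor")
        labels = music_tr_labels(tl, tr_s)
        pre = np.where(labels == ev.index - 2)[0]
        cur = np.where(labels == ev.index - 1)[0]
        windows.append((pre, cur))
    n_pre = min(len(windows[0][0]), len(windows[1][0]))
    n_cur = min(len(windows[0][1]), len(windows[1][1]))
    if n_pre == 0 or n_cur == 0:
        raise ValueError(f"event {event_key}: empty window")
    return tuple(
        np.concatenate([pre[len(pre) - n_pre:], cur[:n_cur]]) for pre, cur in windows
    )


def transition_sum(
    window_features: np.ndarray, cfg: HmmConfig | None = None
) -> tuple[float, bool]:
    """Sum of the expected event index over a 2-state HMM fit of the window.

    Returns (sum, low_confidence): with labels {0, 1} the sum counts TRs
    assigned to the current event, so instant switching gives ~T and a
    switch at TR t* gives ~T - t*.  low_confidence marks windows without
    a genuine state change: either the maximum-posterior path never
    switches, or the two fitted state patterns are nearly identical
    (correlation > 0.9), as happens when the window is homogeneous and
    the placement is noise-driven.
    """
    x = np.asarray(window_features, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("window must span at least 4 TRs")
    seg = fit(x, cfg or HmmConfig(n_events=2))
    s = float(expected_event_index(seg).sum())
    pat_r = float(np.corrcoef(seg.event_patterns[0], seg.event_patterns[1])[0, 1])
    low_confidence = len(find_boundaries(seg)) == 0 or pat_r > 0.9
    return s, low_confidence


def eligible_event_keys(
    tl_v1: EventTimeline, tl_v2: EventTimeline
) -> list[tuple[tuple[str, int], int]]:
    """Events whose incoming transition class genuinely flips between versions.

    Returns (key, same_version) pairs, where same_version is the version
    in which the incoming transition is same-valence.  Events preceded by
    a nostalgic bookend, or preceded by the same class in both versions
    (the published tables contain several), are excluded.
    """
    classes = {}
    for tl in (tl_v1, tl_v2):
        trans = classify_transitions(tl)
        for t in trans:
            classes.setdefault(t.to_event.key, {})[tl.version] = t.klass
    out = []
    for key, by_ver in classes.items():
        if set(by_ver) != {1, 2}:
            continue
        pair = {by_ver[1], by_ver[2]}
        if pair == {TransitionClass.SAME_VALENCE, TransitionClass.DIFFERENT_VALENCE}:
            same_v = 1 if by_ver[1] is TransitionClass.SAME_VALENCE else 2
            out.append((key, same_v))
    return sorted(out)


def valence_timing_contrast(
    group_features: dict[tuple[str, int], np.ndarray],
    timelines: dict[tuple[str, int], EventTimeline],
    n_perm: int = 1000,
    seed: int = 0,
    tr_s: float = 1.5,
    cfg: HmmConfig | None = None,
) -> dict:
    """Same-valence vs different-valence transition-timing contrast.

    group_features maps (piece, version) -> group-mean music-run feature
    matrix on the music TR grid.  Events from both pieces are pooled.
    Observed statistic: one-sample t (mean / SD) of the per-event
    same-minus-different difference in transition sums; the permutation
    null flips each event's class assignment at random.  Also reports the
    mean shift in seconds (difference in TRs x tr_s).
    """
    rows = []
    for piece in sorted({p for p, _ in timelines}):
        tl1, tl2 = timelines[(piece, 1)], timelines[(piece, 2)]
        for key, same_v in eligible_event_keys(tl1, tl2):
            w1, w2 = paired_event_windows(tl1, tl2, key, tr_s)
            sums, flags = {}, {}
            for v, w in ((1, w1), (2, w2)):
                sums[v], flags[v] = transition_sum(group_features[(piece, v)][w], cfg)
            diff_v = 2 if same_v == 1 else 1
            rows.append(
                {
                    "piece": piece,
                    "emotion": key[0],
                    "exemplar_no": key[1],
                    "same_version": same_v,
                    "sum_same": sums[same_v],
                    "sum_diff": sums[diff_v],
                    "diff_tr": sums[same_v] - sums[diff_v],
                    "diff_s": (sums[same_v] - sums[diff_v]) * tr_s,
                    "low_confidence": flags[same_v] or flags[diff_v],
                }
            )
    if len(rows) < 2:
        raise ValueError("need at least 2 eligible events per class")
    table = pd.DataFrame(rows)
    d = table["diff_tr"].to_numpy()

    def tstat(x):
        sd = np.std(x, ddof=1)
        return float(np.mean(x) / sd) if sd > 0 else 0.0

    observed = tstat(d)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=len(d))
        null[i] = tstat(d * signs)
    result = PermutationResult.from_null(observed, null, seed)
    return {
        "result": result,
        "shift_tr": float(np.mean(d)),
        "shift_seconds": float(np.mean(d) * tr_s),
        "events": table,
    }
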