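"""Does an event's evoked spatial pattern depend on what preceded it?

Each musical event occurs in both versions of its piece with a different
predecessor.  If context shapes the representation, two subjects who
heard the event in the same version should show more similar event
patterns than two subjects who heard it in different versions.  The
statistic compares split-half group-mean pattern correlations within
versions (combined by geometric mean, as a reliability-like quantity)
against across-version correlations; significance comes from shuffling
subjects' version labels at the whole-piece level.
"""

from __future__ import annotations

import numpy as np

from ._stats import PermutationResult
from .timeline import EventTimeline, music_tr_labels

__all__ = [
    "event_mean_patterns",
    "split_half_context_stat",
    "version_label_permutation_test",
]

_FLOOR = 1e-6


def event_mean_patterns(
    features: np.ndarray,
    tl: EventTimeline,
    tr_s: float = 1.5,
    half: str = "full",
) -> np.ndarray:
    """Per-event mean pattern, (n_events, F), ordered by event position.

    half="second" averages only the later portion of each event's TRs
    (floor split: an event with 2m or 2m+1 TRs keeps its last m or m+1),
    a control against signal spilling over from the previous event.
    """
    if half not in ("full", "second"):
        raise ValueError("half must be 'full' or 'second'")
    x = np.asarray(features, dtype=float)
    labels = music_tr_labels(tl, tr_s)
    if x.shape[0] != labels.shape[0]:
        raise ValueError(
            f"features have {x.shape[0]} TRs but the music grid has {labels.shape[0]}"
        )
    out = np.empty((len(tl.events), x.shape[1]))
    for i in range(len(tl.events)):
        trs = np.where(labels == i)[0]
        if half == "second":
            trs = trs[len(trs) // 2:]
        if trs.size == 0:
            raise ValueError(f"event {i + 1} has no TRs after halving")
        out[i] = x[trs].mean(axis=0)
    return out


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation between two (n, F) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
    denom[denom == 0] = np.inf
    return np.sum(ac * bc, axis=1) / denom


def _stat(
    patterns: dict[str, np.ndarray],
    versions: dict[str, np.ndarray],
    order: dict[str, np.ndarray],
    floor: float = _FLOOR,
) -> tuple[float, dict]:
    same_by_piece, diff_by_piece, n_floored = [], [], 0
    for piece, pats in patterns.items():
        v = versions[piece]
        halves = {}
        for ver in (1, 2):
            idx = order[piece][v[order[piece]] == ver]
            if len(idx) < 2:
                raise ValueError(f"piece {piece} v{ver}: need >= 2 subjects per group")
            cut = len(idx) // 2
            halves[(ver, 1)] = pats[idx[:cut]].mean(axis=0)
            halves[(ver, 2)] = pats[idx[cut:]].mean(axis=0)
        within = []
        for ver in (1, 2):
            r = float(np.mean(_row_corr(halves[(ver, 1)], halves[(ver, 2)])))
            if r < floor:
                n_floored += 1
                r = floor
            within.append(r)
        same_by_piece.append(float(np.sqrt(within[0] * within[1])))
        cross_pairs = [((1, 1), (2, 1)), ((1, 2), (2, 2)), ((1, 1), (2, 2)), ((1, 2), (2, 1))]
        cross = [float(np.mean(_row_corr(halves[a], halves[b]))) for a, b in cross_pairs]
        diff_by_piece.append(float(np.mean(cross)))
    detail = {
        "same_by_piece": same_by_piece,
        "different_by_piece": diff_by_piece,
        "n_floored": n_floored,
    }
    return float(np.mean(same_by_piece) - np.mean(diff_by_piece)), detail


def _prepare(patterns_by_group):
    """Normalize input to dicts of per-piece stacked patterns and versions.

    Accepted form: {piece: (versions array of 1/2 per subject,
    patterns array (n_subjects, n_events, F))}.
    """
    patterns, versions = {}, {}
    for piece, (v, p) in patterns_by_group.items():
        versions[piece] = np.asarray(v, dtype=int)
        patterns[piece] = np.asarray(p, dtype=float)
        if versions[piece].shape[0] != patterns[piece].shape[0]:
            raise ValueError(f"piece {piece}: versions/patterns length mismatch")
    return patterns, versions


def split_half_context_stat(
    patterns_by_group: dict, seed: int = 0, return_detail: bool = False
):
    """Same-context minus different-context split-half pattern correlation.

    patterns_by_group maps piece -> (per-subject version labels,
    per-subject event x feature pattern stacks, rows keyed identically
    across versions).  Subjects are split into random halves (fixed by
    ``seed``); within-version half-pair correlations are combined by
    geometric mean per piece (floored at 1e-6 if negative), cross-version
    pairs are averaged arithmetically; the statistic is the mean over
    pieces of (same - different).  Zero in expectation when version
    labels carry no information.
    """
    patterns, versions = _prepare(patterns_by_group)
    rng = np.random.default_rng(seed)
    order = {piece: rng.permutation(len(v)) for piece, v in versions.items()}
    stat, detail = _stat(patterns, versions, order)
    return (stat, detail) if return_detail else stat


def version_label_permutation_test(
    patterns_by_group: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the context statistic.

    The null shuffles each subject's version label at the whole-piece
    level; the random half-split (drawn once from ``seed``) is reused for
    the observed statistic and every permutation so only the labels vary.
    """
    patterns, versions = _prepare(patterns_by_group)
    for piece, v in versions.items():
        if len(np.unique(v)) < 2:
            raise ValueError(f"piece {piece}: both versions must be represented")
    rng = np.random.default_rng(seed)
    order = {piece: rng.permutation(len(v)) for piece, v in versions.items()}
    observed, detail = _stat(patterns, versions, order)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = {p: rng.permutation(v) for p, v in versions.items()}
        null[i], _ = _stat(patterns, shuffled, order)
    return PermutationResult.from_null(observed, null, seed, **detail)
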