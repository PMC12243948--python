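"""Tests for whether a region's patterns track event transitions.

Hypothesis-driven: timepoint-by-timepoint pattern correlations should be
higher within a composer-defined event than across adjacent events, with
a null built by shuffling the order of the event blocks (preserving each
event's length).  Data-driven: the fitted HMM's per-TR entropy should
peak at composer-defined transitions, against the same length-preserving
shuffle of event timing.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._stats import PermutationResult
from .eventseg import EventSegmentation, entropy_trace

__all__ = [
    "timepoint_corr",
    "within_across_stat",
    "shuffle_event_lengths",
    "boundary_pattern_test",
    "entropy_match_test",
]


def timepoint_corr(features: np.ndarray) -> np.ndarray:
    """T x T Pearson correlation between per-TR feature patterns.

    Zero-variance rows get correlation 0 (with a warning) rather than NaN.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("features must be (T, F) with T >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in features")
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-variance timepoints; correlations set to 0",
                      stacklevel=2)
        x = x.copy()
        x[bad] = 0.0
        sd = sd.copy()
        sd[bad] = 1.0
    xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    c = (xc @ xc.T) / x.shape[1]
    c[bad, :] = 0.0
    c[:, bad] = 0.0
    np.fill_diagonal(c, np.where(bad, 0.0, 1.0))
    return c


def within_across_stat(corrmat: np.ndarray, tr_labels: np.ndarray) -> float:
    """Mean within-event correlation minus mean across-adjacent-event correlation.

    tr_labels holds the 0-based event index per TR, -1 for TRs belonging
    to no event (silence/interludes), which are excluded.  Across-event
    pairs are restricted to *adjacent* events (labels differing by 1).
    """
    c = np.asarray(corrmat)
    lab = np.asarray(tr_labels)
    if c.shape[0] != c.shape[1] or c.shape[0] != lab.shape[0]:
        raise ValueError("corrmat and tr_labels sizes disagree")
    events = np.unique(lab[lab >= 0])
    if len(events) < 2:
        raise ValueError("need at least 2 labeled events")
    # block sums via one-hot indicators: B[e, f] = sum of c over (e, f) TR pairs
    onehot = (lab[None, :] == events[:, None]).astype(float)
    B = onehot @ c @ onehot.T
    diag_by_event = onehot @ np.diag(c)
    within_sum = float(np.sum(np.diag(B) - diag_by_event)) / 2.0  # drop self-pairs
    n = onehot.sum(axis=1)
    within_cnt = float(np.sum(n * (n - 1)) / 2.0)
    adj = np.where(np.diff(events) == 1)[0]  # label values differing by exactly 1
    across_sum = float(np.sum(B[adj, adj + 1]))
    across_cnt = float(np.sum(n[adj] * n[adj + 1]))
    if across_cnt == 0:
        raise ValueError("no adjacent-event TR pairs")
    return within_sum / within_cnt - across_sum / across_cnt


def shuffle_event_lengths(
    event_lengths: np.ndarray, n_perm: int, seed: int
) -> list[np.ndarray]:
    """Length-preserving null labelings: random reorderings of the event
    blocks laid end-to-end over the labeled TRs.

    Each returned vector has length sum(event_lengths) and assigns event
    index 0..K-1 blockwise in a permuted order (the label value is the
    block's *position* in the permuted sequence, so adjacency in the
    shuffled labeling reflects shuffled-neighbour relationships).
    """
    lengths = np.asarray(event_lengths, dtype=int)
    if (lengths <= 0).any():
        raise ValueError("event lengths must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        order = rng.permutation(len(lengths))
        out.append(np.repeat(np.arange(len(lengths)), lengths[order]))
    return out


def boundary_pattern_test(
    features: np.ndarray,
    tr_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Within-minus-across correlation statistic with its length-preserving null.

    features: (T, F) group-level feature time series aligned with tr_labels.
    One-sided: high values mean patterns are stable within events and
    shift at event boundaries.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    lab = np.asarray(tr_labels)
    c = timepoint_corr(features)
    observed = within_across_stat(c, lab)
    labeled = np.where(lab >= 0)[0]
    sub = c[np.ix_(labeled, labeled)]
    _, lengths = np.unique(lab[labeled], return_counts=True)
    null = np.empty(n_perm)
    for i, perm_lab in enumerate(shuffle_event_lengths(lengths, n_perm, seed)):
        null[i] = within_across_stat(sub, perm_lab)
    return PermutationResult.from_null(observed, null, seed)


def _shuffled_transitions(
    transition_trs: np.ndarray, n_trs: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle event timing preserving segment lengths; return new transition TRs."""
    edges = np.concatenate([[0], np.sort(transition_trs), [n_trs]])
    seg = np.diff(edges)
    perm = rng.permutation(len(seg))
    return np.cumsum(seg[perm])[:-1]


def entropy_match_test(
    seg: EventSegmentation | np.ndarray,
    transition_trs: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    window_tr: int = 0,
) -> PermutationResult:
    """Mean posterior entropy at composer-defined transitions vs shuffled timing.

    Accepts a fitted segmentation or a precomputed entropy trace.  The
    null preserves inter-transition segment lengths and permutes their
    order, then reads the entropy at the shuffled transition TRs.
    window_tr widens each evaluation point to +/- that many TRs, which
    absorbs the one-TR shift hemodynamic-style smoothing introduces.
    """
    trace = (
        entropy_trace(seg)
        if isinstance(seg, EventSegmentation) or np.asarray(seg).ndim == 2
        else np.asarray(seg, dtype=float)
    )
    trs = np.asarray(transition_trs, dtype=int)
    if trs.size == 0:
        raise ValueError("transition list is empty")
    if trs.min() < 0 or trs.max() >= trace.shape[0]:
        raise ValueError("transition TRs out of range")

    def mean_at(points: np.ndarray) -> float:
        if window_tr == 0:
            return float(trace[points].mean())
        idx = np.unique(
            np.clip(
                points[:, None] + np.arange(-window_tr, window_tr + 1)[None, :],
                0,
                trace.shape[0] - 1,
            )
        )
        return float(trace[idx].mean())

    observed = mean_at(trs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = mean_at(_shuffled_transitions(trs, trace.shape[0], rng))
    return PermutationResult.from_null(observed, null, seed)
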