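"""Forward-only HMM for segmenting a time series into K stable events.

The model assumes the listener moves through K events in a fixed order,
each visited exactly once: the transition matrix is zero everywhere
except the diagonal (stay, probability ``diag_prob``) and the first
off-diagonal (advance).  The chain is pinned to start in event 1 and end
in event K.  The last state's row carries only the stay probability (no
exit mass), which makes the prior over boundary placements uniform: the
posterior boundary is then exactly the maximum-likelihood placement, a
property the exhaustive K=2 oracle tests rely on.

Emissions are isotropic Gaussians on row-z-scored data against
row-z-scored event patterns, so the likelihood behaves like pattern
correlation and is scale-invariant.  Fitting alternates a forward-
backward E-step with an M-step that recomputes each event's pattern as
the posterior-weighted mean of the data (re-z-scored) and a single
shared emission variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import entropy as _shannon

__all__ = [
    "HmmConfig",
    "EventSegmentation",
    "forward_backward",
    "fit",
    "entropy_trace",
    "expected_event_index",
    "find_boundaries",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass(frozen=True)
class HmmConfig:
    """Knobs of the event segmentation model.

    diag_prob defaults to (K-1)/T, fixed (not adjusted during fitting).
    init_fracs are the warp factors of the deterministic multi-start
    initializations (0.5 = equal contiguous blocks); the start with the
    best final likelihood wins.
    """

    n_events: int
    diag_prob: float | None = None
    max_em_iter: int = 100
    tol: float = 1e-4
    var_floor: float = 1e-6
    init_fracs: tuple[float, ...] = (0.5, 0.25, 0.75, 0.1, 0.9)

    def resolve_diag(self, n_trs: int) -> float:
        d = self.diag_prob
        if d is None:
            d = (self.n_events - 1) / n_trs
        if not (0 < d < 1):
            raise ValueError(f"diag_prob must lie in (0, 1), got {d}")
        return d


@dataclass
class EventSegmentation:
    """Event-by-timepoint posterior from the constrained HMM."""

    gamma: np.ndarray  # (K, T), columns sum to 1
    event_patterns: np.ndarray  # (K, F)
    log_likelihood: float
    K: int
    T: int
    var: float
    ll_trace: list[float] = field(default_factory=list)
    warning: bool = False  # EM failed to improve / decreased


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a (T, F) matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in data")
    return data


def _log_emissions(x: np.ndarray, patterns: np.ndarray, var: float) -> np.ndarray:
    """(T, K) log density of each z-scored row under each pattern."""
    d2 = (
        np.sum(x**2, axis=1)[:, None]
        - 2 * x @ patterns.T
        + np.sum(patterns**2, axis=1)[None, :]
    )
    F = x.shape[1]
    return -0.5 * (d2 / var + F * (_LOG2PI + np.log(var)))


def forward_backward(
    data: np.ndarray,
    event_patterns: np.ndarray,
    var: float,
    cfg: HmmConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Posterior gamma (K, T) and data log-likelihood for fixed patterns.

    Rows of data and patterns are z-scored before evaluation.  Start is
    pinned to event 1 and the end to event K.
    """
    data = _check_data(data)
    patterns = _zscore_rows(np.asarray(event_patterns, dtype=float))
    K, T = patterns.shape[0], data.shape[0]
    if K > T:
        raise ValueError(f"K={K} exceeds T={T}")
    x = _zscore_rows(data)
    if K == 1:
        logb = _log_emissions(x, patterns, var)[:, 0]
        return np.ones((1, T)), float(np.sum(logb))
    cfg = cfg or HmmConfig(n_events=K)
    d = cfg.resolve_diag(T)
    log_stay, log_adv = np.log(d), np.log1p(-d)
    logb = _log_emissions(x, patterns, var)  # (T, K)

    neg = -np.inf
    alpha = np.full((T, K), neg)
    alpha[0, 0] = logb[0, 0]  # start pinned to event 1
    for t in range(1, T):
        prev = alpha[t - 1]
        stay = prev + log_stay
        adv = np.full(K, neg)
        adv[1:] = prev[:-1] + log_adv
        alpha[t] = logb[t] + np.logaddexp(stay, adv)
    ll = float(alpha[-1, -1])  # end pinned to event K

    beta = np.full((T, K), neg)
    beta[-1, -1] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + logb[t + 1]
        stay = nxt + log_stay
        adv = np.full(K, neg)
        adv[:-1] = nxt[1:] + log_adv
        beta[t] = np.logaddexp(stay, adv)

    logg = alpha + beta
    logg -= logsumexp(logg, axis=1, keepdims=True)
    return np.exp(logg).T, ll


def _init_patterns(x: np.ndarray, K: int, frac: float = 0.5) -> np.ndarray:
    """Means of K contiguous blocks with power-warped edges.

    frac = 0.5 gives equal blocks; smaller/larger fracs squeeze the
    blocks toward the start/end, giving EM deterministic alternative
    basins to escape the degenerate case where a boundary lies near the
    run's edge and equal-block means are nearly identical.
    """
    T = x.shape[0]
    p = np.log(frac) / np.log(0.5)
    edges = (T * np.linspace(0, 1, K + 1) ** p).astype(int)
    edges[0], edges[-1] = 0, T
    pats = []
    for i in range(K):
        a = min(edges[i], T - 1)
        b = max(edges[i + 1], a + 1)
        pats.append(x[a:b].mean(axis=0))
    return _zscore_rows(np.stack(pats))


def _novelty_init(x: np.ndarray, K: int) -> np.ndarray | None:
    """Segment means at the K-1 strongest pattern-novelty peaks.

    Novelty at TR t contrasts the mean within-block correlation on either
    side of t with the cross-block correlation (a checkerboard-kernel
    score on the TR x TR correlation matrix).  Greedy peak picking with a
    minimum separation supplies a data-driven start that escapes the
    frozen-alignment local optima contiguous-block inits share when the
    signal is strong.  Returns None when K-1 separated peaks don't exist.
    """
    T = x.shape[0]
    if K < 2 or T < 2 * K:
        return None
    c = np.corrcoef(x)
    if not np.all(np.isfinite(c)):
        return None
    w = max(2, min(10, T // K))
    nov = np.zeros(T)
    for t in range(1, T):
        a = slice(max(t - w, 0), t)
        b = slice(t, min(t + w, T))
        nov[t] = c[a, a].mean() + c[b, b].mean() - 2 * c[a, b].mean()
    sep = max(2, T // (2 * K))
    picks: list[int] = []
    for t in np.argsort(-nov):
        if t == 0:
            continue
        if all(abs(int(t) - p) >= sep for p in picks):
            picks.append(int(t))
        if len(picks) == K - 1:
            break
    if len(picks) < K - 1:
        return None
    edges = np.concatenate([[0], np.sort(picks), [T]])
    return _zscore_rows(
        np.vstack([x[edges[i]: edges[i + 1]].mean(axis=0) for i in range(K)])
    )


def _em_single(
    x: np.ndarray, cfg: HmmConfig, frac: float, patterns: np.ndarray | None = None
) -> EventSegmentation:
    T, F = x.shape
    K = cfg.n_events
    if patterns is None:
        patterns = _init_patterns(x, K, frac)
    assign = np.linspace(0, K - 1, T).round().astype(int)
    var = max(float(np.mean((x - patterns[assign]) ** 2)), cfg.var_floor)
    best = None
    lls: list[float] = []
    warning = False
    for _ in range(max(cfg.max_em_iter, 1)):
        gamma, ll = forward_backward(x, patterns, var, cfg)
        lls.append(ll)
        if best is None or ll >= best.log_likelihood:
            best = EventSegmentation(
                gamma=gamma, event_patterns=patterns.copy(),
                log_likelihood=ll, K=K, T=T, var=var,
            )
        if len(lls) > 1:
            gain = ll - lls[-2]
            if gain < -1e-8:
                warning = True
                break
            if gain < cfg.tol:
                break
        # M-step
        w = gamma.sum(axis=1)
        w[w == 0] = 1.0
        patterns = _zscore_rows((gamma @ x) / w[:, None])
        d2 = (
            np.sum(x**2, axis=1)[None, :]
            - 2 * patterns @ x.T
            + np.sum(patterns**2, axis=1)[:, None]
        )
        var = max(float(np.sum(gamma * d2) / (T * F)), cfg.var_floor)
    best.ll_trace = lls
    best.warning = warning
    return best


def fit(data: np.ndarray, cfg: HmmConfig | int) -> EventSegmentation:
    """Fit event patterns and posterior by EM.

    Deterministic multi-start: EM runs once from each contiguous-block
    initialization in cfg.init_fracs plus a data-driven novelty-peak
    initialization, and the solution with the highest final
    log-likelihood is returned.  Each run stops when the gain falls below
    cfg.tol or at cfg.max_em_iter; a run whose likelihood decreases
    returns its best-so-far state with ``warning=True``.
    """
    if isinstance(cfg, int):
        cfg = HmmConfig(n_events=cfg)
    data = _check_data(data)
    T, _ = data.shape
    K = cfg.n_events
    if K > T:
        raise ValueError(f"K={K} exceeds T={T}")
    x = _zscore_rows(data)
    if K == 1:
        pattern = _zscore_rows(x.mean(axis=0, keepdims=True))
        var = max(float(np.mean((x - pattern) ** 2)), cfg.var_floor)
        gamma, ll = forward_backward(x, pattern, var, cfg)
        return EventSegmentation(
            gamma=gamma, event_patterns=pattern, log_likelihood=ll,
            K=1, T=T, var=var, ll_trace=[ll],
        )
    best = None
    for frac in cfg.init_fracs or (0.5,):
        seg = _em_single(x, cfg, frac)
        if best is None or seg.log_likelihood > best.log_likelihood:
            best = seg
    nov = _novelty_init(x, K)
    if nov is not None:
        seg = _em_single(x, cfg, 0.5, patterns=nov)
        if seg.log_likelihood > best.log_likelihood:
            best = seg
    return best


def entropy_trace(seg: EventSegmentation | np.ndarray) -> np.ndarray:
    """Per-TR Shannon entropy (nats) of the event posterior.

    High entropy marks uncertainty between adjacent events, the HMM's
    signature of a boundary.  Bounded by [0, ln K].
    """
    gamma = seg.gamma if isinstance(seg, EventSegmentation) else np.asarray(seg)
    return _shannon(gamma, axis=0)


def expected_event_index(seg: EventSegmentation | np.ndarray) -> np.ndarray:
    """Per-TR expectation of the event index under gamma (labels 0..K-1)."""
    gamma = seg.gamma if isinstance(seg, EventSegmentation) else np.asarray(seg)
    return np.arange(gamma.shape[0]) @ gamma


def find_boundaries(seg: EventSegmentation | np.ndarray) -> np.ndarray:
    """TRs where the argmax event index increments (first TR of new event).

    Ties in a gamma column break toward the earlier event.
    """
    gamma = seg.gamma if isinstance(seg, EventSegmentation) else np.asarray(seg)
    path = np.argmax(gamma, axis=0)
    return np.where(np.diff(path) > 0)[0] + 1
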