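"""Synthetic multi-subject data with the study's event structure.

The generator emulates the two-piece / two-version musical event design:
every event has a stable latent spatial pattern; the pattern is perturbed
by a component keyed to the *preceding* event (context effect); the
neural transition into an event is delayed when the incoming transition
crosses valence (timing effect); and the latent signal is mapped into
each subject's voxel space through a subject-specific semi-orthogonal
map, then corrupted by AR(1) + sinusoidal drift + white noise.

A pattern persists through the interlude that follows its event until
the next event's onset (a "lingering" model), so every boundary is a
single well-defined switch TR; those switch TRs are stored as ground
truth for recovery tests.  All generators are pure functions of their
spec and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import timeline as tlmod
from .timeline import (
    Emotion,
    EventTimeline,
    TransitionClass,
    Valence,
    all_builtin_timelines,
    catalogue_events,
    classify_transitions,
    music_tr_labels,
)

__all__ = [
    "SimSpec",
    "SubjectData",
    "SimDataset",
    "make_event_patterns",
    "simulate_subject",
    "simulate_cohort",
    "simulate_button_presses",
    "simulate_ratings",
    "make_surface_graph",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic cohort.

    snr is the ratio of event-signal SD to total noise SD per voxel.
    context_shift is the fraction of each event's pattern replaced by a
    perturbation keyed to (event, predecessor); timing_delay_tr is the
    number of extra TRs the previous pattern persists when the incoming
    transition crosses valence (4 TRs = 6 s at TR 1.5 s).
    """

    n_subjects: int = 40
    n_units: int = 200
    n_features: int = 40
    snr: float = 0.5
    ar_coef: float = 0.4
    drift_amplitude: float = 0.3
    white_frac: float = 0.05
    context_shift: float = 0.5
    timing_delay_tr: int = 4
    hrf_smooth_tr: float = 2.0
    tr_s: float = 1.5
    align_trs: int = 496
    shared_voxel_map: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_units <= 0 or self.n_features <= 0:
            raise ValueError("sizes must be positive")
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2")
        if self.n_units < self.n_features:
            raise ValueError("n_units must be >= n_features (semi-orthogonal maps)")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must lie in [0, 1)")
        if not (0 <= self.context_shift <= 1):
            raise ValueError("context_shift must lie in [0, 1]")
        if min(self.drift_amplitude, self.white_frac, self.hrf_smooth_tr) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.timing_delay_tr < 0:
            raise ValueError("timing_delay_tr must be nonnegative")


@dataclass
class SubjectData:
    """One subject's time x unit matrix on a fixed TR grid, z-scored per unit."""

    data: np.ndarray  # (T, n_units)
    tr_s: float
    piece: str | None = None
    version: int | None = None
    kind: str = "music"
    meta: dict = field(default_factory=dict)

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass
class SimDataset:
    """Cohort of simulated subjects plus the ground truth that generated them."""

    spec: SimSpec
    subjects: list[dict[str, SubjectData]]
    versions: np.ndarray  # per-subject version assignment (applies to both pieces)
    keys: list[tuple[str, int]]  # catalogue order of the unique events
    patterns: np.ndarray  # base event patterns, (n_events_total, n_features)
    latent: dict[tuple[str, int], np.ndarray]  # (piece, version) -> (T, F) clean course
    boundaries: dict[tuple[str, int], np.ndarray]  # actual switch TRs (with delays)
    onset_trs: dict[tuple[str, int], np.ndarray]  # composer onset TRs per event
    align_latent: np.ndarray  # shared alignment-run course, (T_align, F)
    subject_maps: list[np.ndarray]  # (F, n_units) semi-orthogonal maps

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_mean(self, piece: str, version: int) -> np.ndarray:
        """Average music-run data over the subjects who heard this version."""
        mats = [
            s[piece].data
            for s, v in zip(self.subjects, self.versions)
            if v == version
        ]
        if not mats:
            raise ValueError(f"no subjects heard {piece} v{version}")
        return np.mean(mats, axis=0)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def make_event_patterns(
    n_features: int,
    keys: Sequence[tuple[str, int]],
    seed: int = 0,
) -> np.ndarray:
    """Zero-mean unit-variance latent pattern per unique event.

    Independent Gaussian rows, so expected pairwise correlation is ~0 for
    dimensions in the tens.  Deterministic given the seed.
    """
    if n_features < 2:
        raise ValueError("n_features must be at least 2")
    rng = np.random.default_rng(_stable_seed("patterns", seed))
    return _zscore_rows(rng.standard_normal((len(keys), n_features)))


def _perturbation(key, pred_key, n_features: int, seed: int) -> np.ndarray:
    """Context perturbation keyed to (event, predecessor); shared by every
    subject who hears that ordering, which is what makes same-version
    subjects more alike than cross-version pairs."""
    rng = np.random.default_rng(_stable_seed("context", seed, key, pred_key))
    return _zscore_rows(rng.standard_normal((1, n_features)))[0]


def _causal_smooth(x: np.ndarray, width_tr: float) -> np.ndarray:
    """Causal half-Gaussian smoothing along time (axis 0)."""
    if width_tr <= 0:
        return x
    half = int(np.ceil(3 * width_tr))
    w = np.exp(-0.5 * (np.arange(half + 1) / width_tr) ** 2)
    w /= w.sum()
    out = np.zeros_like(x)
    for j, wj in enumerate(w):
        if j == 0:
            out += wj * x
        else:
            out[j:] += wj * x[:-j]
            out[:j] += wj * x[:1]  # pad with the initial pattern
    return out


def latent_event_course(
    spec: SimSpec,
    tl: EventTimeline,
    patterns: Mapping[tuple[str, int], np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clean latent (T, F) course for one piece version, before smoothing.

    Returns (course, switch_trs, onset_trs).  switch_trs are the 15 TRs at
    which the latent pattern actually changes: the event onset TR, plus
    timing_delay_tr when the incoming transition is different-valence.
    """
    n_tr = tlmod.music_tr_count(spec.tr_s, tl.total_music_s)
    trans = classify_transitions(tl)
    onset_trs = np.array(
        [int(np.ceil(e.onset_s / spec.tr_s)) for e in tl.events], dtype=int
    )
    starts = onset_trs.copy()
    for i in range(1, len(tl.events)):
        if trans[i - 1].klass is TransitionClass.DIFFERENT_VALENCE:
            starts[i] = min(starts[i] + spec.timing_delay_tr, n_tr - 1)
    eff = np.zeros((len(tl.events), spec.n_features))
    for i, e in enumerate(tl.events):
        base = patterns[e.key]
        if i > 0 and spec.context_shift > 0:
            pred = tl.events[i - 1]
            pert = _perturbation(e.key, pred.key, spec.n_features, spec.seed)
            v = (1 - spec.context_shift) * base + spec.context_shift * pert
        else:
            v = base
        eff[i] = _zscore_rows(v[None, :])[0]
    course = np.empty((n_tr, spec.n_features))
    bounds = np.concatenate([starts, [n_tr]])
    for i in range(len(tl.events)):
        course[bounds[i]: bounds[i + 1]] = eff[i]
    return course, starts[1:].copy(), onset_trs


def _noise(rng: np.random.Generator, n_tr: int, n_units: int, spec: SimSpec) -> np.ndarray:
    """AR(1) + sinusoidal drift + white noise, unit-SD stationary mixture."""
    w = rng.standard_normal((n_tr, n_units)) * np.sqrt(1 - spec.ar_coef**2)
    ar = np.empty_like(w)
    ar[0] = rng.standard_normal(n_units)
    for t in range(1, n_tr):
        ar[t] = spec.ar_coef * ar[t - 1] + w[t]
    t = np.arange(n_tr)[:, None] / n_tr
    cycles = rng.uniform(0.5, 2.5, n_units)[None, :]
    phase = rng.uniform(0, 2 * np.pi, n_units)[None, :]
    drift = np.sin(2 * np.pi * cycles * t + phase)
    white = rng.standard_normal((n_tr, n_units))
    return (
        np.sqrt(1 - spec.white_frac) * ar
        + np.sqrt(spec.white_frac) * white
        + spec.drift_amplitude * drift
    )


def _subject_map(rng: np.random.Generator, spec: SimSpec) -> np.ndarray:
    """(F, U) map with orthonormal rows: latent features -> voxels."""
    q, _ = np.linalg.qr(rng.standard_normal((spec.n_units, spec.n_features)))
    return q.T


def simulate_subject(
    spec: SimSpec,
    tl: EventTimeline,
    patterns: Mapping[tuple[str, int], np.ndarray],
    seed: int | None = None,
    subject_map: np.ndarray | None = None,
) -> SubjectData:
    """Simulate one music run (597 TRs at defaults) for one subject.

    signal = event-latent course (context shift + valence-dependent delay
    applied), causally smoothed, mapped to voxels; data = snr * z(signal)
    + noise, z-scored per voxel.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    course, switches, _ = latent_event_course(spec, tl, patterns)
    course = _causal_smooth(course, spec.hrf_smooth_tr)
    if subject_map is None:
        subject_map = _subject_map(rng, spec)
    sig = _zscore_cols(course @ subject_map)
    data = _zscore_cols(spec.snr * sig + _noise(rng, len(course), spec.n_units, spec))
    return SubjectData(
        data=data,
        tr_s=spec.tr_s,
        piece=tl.piece,
        version=tl.version,
        kind="music",
        meta={"switch_trs": switches},
    )


def simulate_cohort(
    spec: SimSpec,
    timelines: Mapping[tuple[str, int], EventTimeline] | None = None,
) -> SimDataset:
    """Simulate the full counterbalanced cohort.

    Each subject hears one version (alternating 1, 2, 1, 2, ... so halves
    differ by at most one) of both pieces, plus a shared alignment run: a
    common smooth latent course pushed through the subject's own map, from
    which functional alignment can be learned on held-out data.
    """
    if spec.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if timelines is None:
        timelines = all_builtin_timelines()
    cat = catalogue_events(timelines)
    keys = sorted(cat.keys())
    pat = make_event_patterns(spec.n_features, keys, seed=spec.seed)
    patterns = {k: pat[i] for i, k in enumerate(keys)}

    latent, boundaries, onset_trs = {}, {}, {}
    for (piece, version), tl in sorted(timelines.items()):
        course, switches, onsets = latent_event_course(spec, tl, patterns)
        latent[(piece, version)] = course
        boundaries[(piece, version)] = switches
        onset_trs[(piece, version)] = onsets

    master = np.random.default_rng(_stable_seed("cohort", spec.seed))
    align_latent = _zscore_cols(
        gaussian_filter1d(
            master.standard_normal((spec.align_trs, spec.n_features)),
            sigma=2.0,
            axis=0,
        )
    )
    shared_map = _subject_map(master, spec)

    pieces = sorted({p for p, _ in timelines})
    versions = np.array([1 + (i % 2) for i in range(spec.n_subjects)])
    subjects, maps = [], []
    for i in range(spec.n_subjects):
        srng = np.random.default_rng(_stable_seed("subject", spec.seed, i))
        smap = shared_map if spec.shared_voxel_map else _subject_map(srng, spec)
        maps.append(smap)
        runs: dict[str, SubjectData] = {}
        for piece in pieces:
            tl = timelines[(piece, int(versions[i]))]
            runs[piece] = simulate_subject(
                spec, tl, patterns,
                seed=_stable_seed("run", spec.seed, i, piece),
                subject_map=smap,
            )
        asig = _zscore_cols(align_latent @ smap)
        arng = np.random.default_rng(_stable_seed("align", spec.seed, i))
        adata = _zscore_cols(
            spec.snr * asig + _noise(arng, spec.align_trs, spec.n_units, spec)
        )
        runs["align"] = SubjectData(
            data=adata, tr_s=spec.tr_s, kind="align", meta={}
        )
        subjects.append(runs)
    return SimDataset(
        spec=spec,
        subjects=subjects,
        versions=versions,
        keys=keys,
        patterns=pat,
        latent=latent,
        boundaries=boundaries,
        onset_trs=onset_trs,
        align_latent=align_latent,
        subject_maps=maps,
    )


def simulate_button_presses(
    tl: EventTimeline,
    latency_mean_s: float = 3.0,
    latency_context_penalty_s: float = 9.0,
    n_raters: int = 36,
    press_prob: float = 0.5,
    spurious_rate_per_min: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Continuous-rating button presses for one piece version.

    Each rater marks an event with probability press_prob (about half of
    real raters select the intended label during an event), turning the
    intended emotion ON near its onset with a lognormal latency
    (penalized by latency_context_penalty_s when the incoming transition
    crosses valence) and OFF near its offset; uniformly spurious presses
    are added on top.  Columns: rater, label, action, time_s.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if not (0 < press_prob <= 1):
        raise ValueError("press_prob must lie in (0, 1]")
    rng = np.random.default_rng(_stable_seed("presses", seed, tl.piece, tl.version))
    trans = classify_transitions(tl)
    sigma = 0.4
    mu = np.log(max(latency_mean_s, 1e-6)) - sigma**2 / 2
    rows = []
    for r in range(n_raters):
        for i, e in enumerate(tl.events):
            if rng.uniform() > press_prob:
                continue
            lat = rng.lognormal(mu, sigma)
            if i > 0 and trans[i - 1].klass is TransitionClass.DIFFERENT_VALENCE:
                lat += latency_context_penalty_s
            on = e.onset_s + lat
            # raters notice the change, not the composer's offset: the label
            # goes off when the next event arrives (or the piece ends)
            end = tl.events[i + 1].onset_s if i + 1 < len(tl.events) else e.offset_s
            off = end + rng.normal(0, 1.5)
            on = float(np.clip(on, 0, tl.total_music_s))
            off = float(np.clip(max(off, on + 0.5), 0, tl.total_music_s))
            rows.append((r, e.emotion.value, "on", on))
            rows.append((r, e.emotion.value, "off", off))
        n_spur = rng.poisson(spurious_rate_per_min * tl.total_music_s / 60.0)
        for _ in range(n_spur):
            rows.append(
                (
                    r,
                    rng.choice([e.value for e in Emotion]),
                    rng.choice(["on", "off"]),
                    float(rng.uniform(0, tl.total_music_s)),
                )
            )
    df = pd.DataFrame(rows, columns=["rater", "label", "action", "time_s"])
    return df.sort_values(["rater", "time_s"], kind="stable").reset_index(drop=True)


_RATING_EMOTIONS = [e.value for e in Emotion]


def simulate_ratings(
    timelines: Mapping[tuple[str, int], EventTimeline] | None = None,
    n_subjects: int = 40,
    context_effect: float = 0.5,
    noise_sd: float = 1.0,
    versions: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrospective 5-emotion ratings (1-7) per subject x event.

    Rating vector = intended-emotion profile + event signature (shared by
    everyone, drives baseline inter-subject agreement) + version-keyed
    offset scaled by context_effect + subject noise, rounded and clipped.
    """
    if context_effect < 0:
        raise ValueError("context_effect must be nonnegative")
    if timelines is None:
        timelines = all_builtin_timelines()
    if versions is None:
        versions = np.array([1 + (i % 2) for i in range(n_subjects)])
    rng = np.random.default_rng(_stable_seed("ratings", seed))
    k = len(_RATING_EMOTIONS)

    def _sig(*parts):
        r = np.random.default_rng(_stable_seed("ratingsig", seed, *parts))
        return r.standard_normal(k)

    rows = []
    for s in range(n_subjects):
        v = int(versions[s])
        for piece in ("A", "B"):
            tl = timelines[(piece, v)]
            for e in tl.events:
                base = np.full(k, 2.0)
                base[_RATING_EMOTIONS.index(e.emotion.value)] = 6.0
                vec = (
                    base
                    + _sig(e.key)
                    + context_effect * _sig(e.key, "v", v)
                    + rng.normal(0, noise_sd, k)
                )
                vec = np.clip(np.round(vec), 1, 7).astype(int)
                rows.append(
                    {
                        "subject": s,
                        "piece": piece,
                        "version": v,
                        "emotion": e.emotion.value,
                        "exemplar_no": e.exemplar_no,
                        **dict(zip(_RATING_EMOTIONS, vec)),
                        "vividness": int(rng.integers(2, 8)),
                        "surprise": int(rng.integers(1, 8)),
                        "enjoyment": int(rng.integers(1, 8)),
                    }
                )
    return pd.DataFrame(rows)


def make_surface_graph(n_rows: int, n_cols: int) -> nx.Graph:
    """Triangulated grid graph standing in for a cortical surface mesh.

    8-neighbour connectivity: vertex degree <= 8, corners have degree 3,
    and the graph is connected.  Node ids are row * n_cols + col.
    """
    if n_rows * n_cols < 9:
        raise ValueError("surface graph needs at least 9 vertices")
    g = nx.Graph()
    for r in range(n_rows):
        for c in range(n_cols):
            g.add_node(r * n_cols + c, row=r, col=c)
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    g.add_edge(r * n_cols + c, rr * n_cols + cc)
    return g


def write_graph(g: nx.Graph, path) -> None:
    nx.write_edgelist(g, path, delimiter="\t", data=False)


def read_graph(path) -> nx.Graph:
    return nx.read_edgelist(path, delimiter="\t", nodetype=int)
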