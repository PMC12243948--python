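"""Design-phase power harness: how many subjects does boundary detection need?

Simulates cohorts at varying N, fits the group HMM, scores the match
between recovered and true boundaries against a length-preserving
shuffle null, and reports the fraction of simulations reaching
significance at the design alpha (0.005, chosen to survive correction
across brain regions).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._stats import PermutationResult
from .eventseg import HmmConfig, find_boundaries, fit
from .synth import SimSpec, simulate_cohort
from .timeline import builtin_timeline

__all__ = ["boundary_match_z", "match_fraction", "power_curve"]


def match_fraction(
    true_trs: np.ndarray, recovered_trs: np.ndarray, tol_tr: int = 1
) -> float:
    """Fraction of true boundaries with a recovered boundary within +/- tol."""
    true_trs = np.asarray(true_trs)
    recovered_trs = np.asarray(recovered_trs)
    if true_trs.size == 0:
        raise ValueError("no true boundaries")
    if recovered_trs.size == 0:
        return 0.0
    d = np.abs(true_trs[:, None] - recovered_trs[None, :])
    return float(np.mean(d.min(axis=1) <= tol_tr))


def boundary_match_z(
    group_data: np.ndarray,
    true_boundary_trs: np.ndarray,
    K: int,
    n_perm: int = 1000,
    seed: int = 0,
    tol_tr: int = 1,
    cfg: HmmConfig | None = None,
) -> PermutationResult:
    """Agreement between HMM-recovered and musical boundaries, vs chance.

    Observed: fraction of true boundaries matched within +/- tol_tr by the
    group-fit HMM's boundaries.  Null: shuffle the true boundaries'
    segment lengths and re-score against the same recovered set.
    """
    seg = fit(np.asarray(group_data, dtype=float), cfg or HmmConfig(n_events=K))
    recovered = find_boundaries(seg)
    observed = match_fraction(true_boundary_trs, recovered, tol_tr)
    T = seg.T
    edges = np.concatenate([[0], np.sort(np.asarray(true_boundary_trs)), [T]])
    lengths = np.diff(edges)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = np.cumsum(lengths[rng.permutation(len(lengths))])[:-1]
        null[i] = match_fraction(shuffled, recovered, tol_tr)
    res = PermutationResult.from_null(observed, null, seed)
    res.extra["recovered_trs"] = recovered.tolist()
    return res


def power_curve(
    spec: SimSpec,
    n_grid: list[int],
    alpha: float = 0.005,
    n_reps: int = 100,
    n_perm: int = 200,
    piece: str = "A",
    version: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Power to detect boundary structure as a function of sample size.

    For each N: simulate a cohort, average the version-matched music runs,
    fit the HMM with K = event count, and test the boundary match; power
    is the fraction of n_reps repetitions with p < alpha.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tl = builtin_timeline(piece, version)
    rows = []
    for n in n_grid:
        hits = 0
        for rep in range(n_reps):
            s = replace(spec, n_subjects=max(n, 2), seed=(seed * 100003 + rep) % (2**31))
            ds = simulate_cohort(s, {(piece, version): tl} | {
                (piece, 3 - version): builtin_timeline(piece, 3 - version)
            })
            group = ds.group_mean(piece, version)
            res = boundary_match_z(
                group,
                ds.boundaries[(piece, version)],
                K=len(tl.events),
                n_perm=n_perm,
                seed=(seed * 7919 + rep) % (2**31),
            )
            hits += res.p < alpha
        rows.append({"n_subjects": n, "power": hits / n_reps, "alpha": alpha,
                     "n_reps": n_reps})
    return pd.DataFrame(rows)
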