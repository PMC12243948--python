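"""Deterministic shared response model (SRM) for functional alignment.

Anatomical alignment is too coarse to match fine-grained response
patterns across brains, so subjects are aligned functionally: given each
subject's time x voxel matrix D_i from a held-out stimulus, find a voxel
x feature transform W_i with orthonormal columns such that D_i W_i ~ S,
the feature time course shared across subjects.  The fit alternates a
shared-response update (mean of projected subjects) with an orthogonal
Procrustes update of each transform, which makes the summed squared
residual non-increasing and the whole procedure deterministic given the
seed used for initialization.  Transforms fit on the held-out run are
then applied to the analysis runs, keeping fitting and analysis data
strictly separate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import SubjectData

__all__ = ["SharedSpace", "fit_srm", "transform", "regress_out"]

DEFAULT_K = 80  # 10% of the largest region this design uses (~800 voxels)


@dataclass
class SharedSpace:
    """Per-subject orthonormal transforms plus the shared time course."""

    transforms: list[np.ndarray]  # each (n_units_i, k)
    shared_ts: np.ndarray  # (T, k), rows = alignment-run TRs
    k: int
    fit_log: list[float]  # objective value per iteration (index 0 = init)
    seed: int = 0

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "shared_ts.tsv", self.shared_ts, delimiter="\t")
        for i, w in enumerate(self.transforms):
            np.savetxt(outdir / f"transform_{i:03d}.tsv", w, delimiter="\t")
        (outdir / "meta.json").write_text(
            json.dumps(
                {
                    "k": self.k,
                    "seed": self.seed,
                    "n_subjects": len(self.transforms),
                    "n_iter": len(self.fit_log) - 1,
                    "objective": self.fit_log,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, outdir: str | Path) -> "SharedSpace":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        transforms = [
            np.loadtxt(outdir / f"transform_{i:03d}.tsv", delimiter="\t", ndmin=2)
            for i in range(meta["n_subjects"])
        ]
        return cls(
            transforms=transforms,
            shared_ts=np.loadtxt(outdir / "shared_ts.tsv", delimiter="\t", ndmin=2),
            k=meta["k"],
            fit_log=list(meta["objective"]),
            seed=meta["seed"],
        )


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, SubjectData):
        x = x.data
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in subject data")
    return x


def _objective(mats: list[np.ndarray], ws: list[np.ndarray], s: np.ndarray) -> float:
    """Reconstruction error sum_i ||X_i - S W_i'||^2.

    Both alternating updates (S = mean of projections, W by orthogonal
    Procrustes) are exact minimizers of this objective, so the logged
    sequence is non-increasing; ||S W'|| is invariant to W because the
    columns of W are orthonormal.
    """
    return float(sum(np.sum((x - s @ w.T) ** 2) for x, w in zip(mats, ws)))


def _procrustes(a: np.ndarray) -> np.ndarray:
    """argmin_{W: W'W=I} ||XW - S|| for a = X'S, via SVD."""
    u, _, vt = np.linalg.svd(a, full_matrices=False)
    return u @ vt


def fit_srm(
    data: list, k: int = DEFAULT_K, n_iter: int = 10, seed: int = 0
) -> SharedSpace:
    """Fit the shared space on held-out (alignment-run) data.

    All subjects must share the same number of timepoints; k must not
    exceed any subject's voxel count nor T.  Initialization draws random
    orthonormal transforms (QR of seeded Gaussians); n_iter = 0 returns
    that initialization with its objective logged.
    """
    mats = [_as_matrix(d) for d in data]
    T = mats[0].shape[0]
    if any(m.shape[0] != T for m in mats):
        raise ValueError("all subjects must share the same number of timepoints")
    if any(k > m.shape[1] for m in mats) or k > T:
        raise ValueError(f"k={k} exceeds a subject's unit count or T={T}")
    rng = np.random.default_rng(seed)
    ws = []
    for m in mats:
        q, _ = np.linalg.qr(rng.standard_normal((m.shape[1], k)))
        ws.append(q)
    s = np.mean([x @ w for x, w in zip(mats, ws)], axis=0)
    log = [_objective(mats, ws, s)]
    for _ in range(n_iter):
        ws = [_procrustes(x.T @ s) for x in mats]
        s = np.mean([x @ w for x, w in zip(mats, ws)], axis=0)
        log.append(_objective(mats, ws, s))
    return SharedSpace(transforms=ws, shared_ts=s, k=k, fit_log=log, seed=seed)


def transform(subject, space: SharedSpace, subject_index: int) -> np.ndarray:
    """Project one subject's run into the shared feature space."""
    x = _as_matrix(subject)
    w = space.transforms[subject_index]
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"subject has {x.shape[1]} units but transform expects {w.shape[0]}"
        )
    return x @ w


def regress_out(features: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualize feature columns against nuisance columns (+ intercept).

    Residuals are orthogonal to the nuisance space.  Collinear nuisance
    columns are harmless (minimum-norm solve) but trigger a warning.
    """
    y = np.asarray(features, dtype=float)
    x = np.asarray(nuisance, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and nuisance must share timepoints")
    if x.shape[1] >= x.shape[0]:
        raise ValueError("more nuisance columns than timepoints")
    design = np.column_stack([np.ones(x.shape[0]), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient nuisance design; collinear columns contribute nothing",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta
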