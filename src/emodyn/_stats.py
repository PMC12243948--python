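"""Shared container for permutation-test results."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PermutationResult"]


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null.

    z is (observed - mean(null)) / sd(null); p uses the plus-one rule
    (1 + #{null >= observed}) / (1 + n_perm), one-sided, so p is never 0.
    """

    observed: float
    null_values: np.ndarray
    n_perm: int
    seed: int
    extra: dict = field(default_factory=dict)

    @property
    def z(self) -> float:
        sd = float(np.std(self.null_values))
        mean = float(np.mean(self.null_values))
        if sd == 0:
            # degenerate null: no deviation -> 0, any deviation -> undefined
            return 0.0 if self.observed == mean else float("nan")
        return (self.observed - mean) / sd

    @property
    def p(self) -> float:
        ge = int(np.sum(np.asarray(self.null_values) >= self.observed))
        return (1 + ge) / (1 + self.n_perm)

    @classmethod
    def from_null(
        cls, observed: float, null_values: np.ndarray, seed: int, **extra
    ) -> "PermutationResult":
        null_values = np.asarray(null_values, dtype=float)
        return cls(
            observed=float(observed),
            null_values=null_values,
            n_perm=len(null_values),
            seed=int(seed),
            extra=dict(extra),
        )

    def to_dict(self) -> dict:
        d = {
            "observed": self.observed,
            "z": self.z,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        d.update(self.extra)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))

    def save_null(self, path: str | Path) -> None:
        np.savetxt(path, self.null_values, fmt="%.10g", delimiter="\t")
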