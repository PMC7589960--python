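"""Balanced two-way crossed fixed-effects designs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TwoWayDesign:
    """Observation-aligned labels for a balanced A x B crossed design.

    ``a`` and ``b`` are per-observation level labels (same length); every
    (a, b) cell must contain the same number of observations. Both
    factors are treated as fixed.
    """

    a_name: str
    b_name: str
    a: tuple
    b: tuple

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("factor label vectors must have equal length")
        counts: dict[tuple, int] = {}
        for cell in zip(self.a, self.b):
            counts[cell] = counts.get(cell, 0) + 1
        n_cells = len(self.a_levels) * len(self.b_levels)
        if len(counts) != n_cells or len(set(counts.values())) != 1:
            raise ValueError("design must be balanced and fully crossed")

    @property
    def a_levels(self) -> list:
        return sorted(set(self.a), key=str)

    @property
    def b_levels(self) -> list:
        return sorted(set(self.b), key=str)

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def replicates(self) -> int:
        return self.n // (len(self.a_levels) * len(self.b_levels))

    @property
    def df(self) -> dict[str, int]:
        """Degrees of freedom: A, B, A x B, residual, total."""
        na, nb, n = len(self.a_levels), len(self.b_levels), self.n
        return {
            self.a_name: na - 1,
            self.b_name: nb - 1,
            f"{self.a_name} x {self.b_name}": (na - 1) * (nb - 1),
            "Residual": n - na * nb,
            "Total": n - 1,
        }

    @classmethod
    def full(cls, a_name, a_levels, b_name, b_levels, replicates) -> "TwoWayDesign":
        """Standard-order design: A slowest, then B, then replicate."""
        a, b = [], []
        for la in a_levels:
            for lb in b_levels:
                a.extend([la] * replicates)
                b.extend([lb] * replicates)
        return cls(a_name, b_name, tuple(a), tuple(b))

    def indicator(self, labels) -> np.ndarray:
        """0/1 dummy matrix (n x levels) for a label vector, levels sorted."""
        labels = list(labels)
        levels = sorted(set(labels), key=str)
        out = np.zeros((len(labels), len(levels)))
        for i, lab in enumerate(labels):
            out[i, levels.index(lab)] = 1.0
        return out
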