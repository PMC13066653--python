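"""Labeled symmetric distance matrices shared by both analysis tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Symmetric distances with row/column labels.

    ``matrix`` holds the working distances (Euclidean for morphology,
    JC69-corrected substitutions/site for sequences); ``p`` optionally
    retains raw proportions of differing sites.
    """

    labels: list[str]
    matrix: np.ndarray
    p: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])
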