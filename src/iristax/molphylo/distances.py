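"""Pairwise evolutionary distances under the Jukes-Cantor (JC69) model.

The p-distance is the mismatch fraction over sites where both sequences
carry a determined base (gaps and N excluded pairwise).  The JC69
correction is d = -(3/4) ln(1 - 4p/3), the expected number of
substitutions per site under equal base frequencies and a single rate.
It diverges as p -> 3/4, so saturated pairs raise rather than returning
an arbitrary large value.
"""

from __future__ import annotations

import numpy as np

from ..distance import DistanceMatrix
from .alignment import Alignment, AlignmentError

__all__ = ["jc69_correct", "jc69_distance_matrix", "SaturationError"]


class SaturationError(ValueError):
    pass


def jc69_correct(p: float) -> float:
    """JC69 distance for a mismatch proportion p in [0, 3/4)."""
    if not 0.0 <= p:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p-distance {p:.4f} >= 3/4: JC69 distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc69_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All pairwise JC69 distances; p-distances retained alongside."""
    codes = aln.encoded()
    return jc69_from_codes(codes, list(aln.ids))


def jc69_from_codes(codes: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = codes.shape[0]
    determined = codes < 4
    pmat = np.zeros((n, n))
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = determined[i] & determined[j]
            m = int(both.sum())
            if m == 0:
                raise AlignmentError(
                    f"pair {labels[i]}, {labels[j]} shares no comparable site"
                )
            p = float(np.count_nonzero(codes[i, both] != codes[j, both])) / m
            if p >= 0.75:
                raise SaturationError(
                    f"pair {labels[i]}, {labels[j]}: p={p:.4f} >= 3/4 (saturated)"
                )
            pmat[i, j] = pmat[j, i] = p
            dmat[i, j] = dmat[j, i] = jc69_correct(p)
    return DistanceMatrix(labels=labels, matrix=dmat, p=pmat)
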