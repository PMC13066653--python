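"""Haplotype collapsing: group identical sequence variants per species.

Accessions whose sequences agree at every site where both are
determined share a haplotype.  By default gaps and N act as wildcards
(missing data compatible with any base); strict mode requires literal
identity.  Wildcard grouping can be ambiguous — a sequence compatible
with two established haplotypes is assigned to the first-seen group and
the ambiguity is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment

log = logging.getLogger(__name__)

__all__ = ["HaplotypeTable", "collapse_haplotypes", "pairwise_differences"]


@dataclass
class HaplotypeTable:
    """Haplotype groups with representative sequences and difference counts."""

    haplotypes: dict[str, list[str]]        # haplotype id -> member accessions
    representatives: dict[str, str]         # haplotype id -> sequence
    differences: dict[tuple[str, str], int]  # (hap_i, hap_j) -> determined-site diffs

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def pairwise_differences(seq_a: str, seq_b: str) -> int:
    """Differing sites where both sequences carry a determined base."""
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    determined = ~(np.isin(a, [b"-", b"N"]) | np.isin(b, [b"-", b"N"]))
    return int(np.count_nonzero((a != b) & determined))


def _compatible(seq_a: str, seq_b: str) -> bool:
    return pairwise_differences(seq_a, seq_b) == 0


def collapse_haplotypes(
    aln: Alignment, scope: str | None = None, strict: bool = False
) -> HaplotypeTable:
    """Group sequences into haplotypes within ``scope`` (a species, or all).

    Greedy first-seen grouping in alignment order: deterministic, and in
    strict mode equivalent to grouping by literal sequence identity.
    """
    if scope is None:
        indices = list(range(aln.n))
    else:
        indices = aln.records_for_species(scope)
        if not indices:
            raise ValueError(f"no sequences for species {scope!r}")
    groups: list[list[int]] = []
    for i in indices:
        matches = []
        for g, members in enumerate(groups):
            rep = aln.seqs[members[0]]
            same = aln.seqs[i] == rep if strict else _compatible(aln.seqs[i], rep)
            if same:
                matches.append(g)
        if len(matches) > 1:
            log.warning(
                "accession %s compatible with %d haplotypes; assigned to first",
                aln.ids[i], len(matches),
            )
        if matches:
            groups[matches[0]].append(i)
        else:
            groups.append([i])
    hap_ids = [f"H{k + 1}" for k in range(len(groups))]
    haplotypes = {h: [aln.ids[i] for i in members] for h, members in zip(hap_ids, groups)}
    representatives = {h: aln.seqs[members[0]] for h, members in zip(hap_ids, groups)}
    differences = {}
    for x in range(len(groups)):
        for y in range(x + 1, len(groups)):
            d = pairwise_differences(
                representatives[hap_ids[x]], representatives[hap_ids[y]]
            )
            differences[(hap_ids[x], hap_ids[y])] = d
    return HaplotypeTable(haplotypes, representatives, differences)
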