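"""Aligned nucleotide sequences with accession and species labels.

FASTA description lines follow ``accession|species``; a bare accession
is accepted, in which case the species can be supplied through a
two-column mapping file.  Sequences are normalized to uppercase,
``U`` is mapped to ``T`` and any character outside ``{A,C,G,T,-,N}``
becomes ``N`` with a logged warning.  Gaps and ``N`` are treated as
missing data downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "AlignmentError",
    "read_alignment",
    "read_species_map",
    "write_alignment",
]

_VALID = set("ACGT-N")
# nucleotide codes: A=0 C=1 G=2 T=3, missing (gap/N) = 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}


class AlignmentError(ValueError):
    pass


def _normalize(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        log.warning("record %s: characters %s mapped to N", name, bad)
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with accession + species labels."""

    ids: list[str]
    species: list[str]
    seqs: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise AlignmentError("alignment needs at least 2 records")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            ragged = [
                i for i, s in zip(self.ids, self.seqs)
                if len(s) != len(self.seqs[0])
            ]
            raise AlignmentError(f"ragged sequence lengths; offending records: {ragged}")
        self.seqs = [_normalize(s, i) for i, s in zip(self.ids, self.seqs)]
        for i, s in zip(self.ids, self.seqs):
            if all(c in "-N" for c in s):
                raise AlignmentError(f"record {i} has no determined site")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 matrix; A=0 C=1 G=2 T=3, missing=4."""
        return np.array(
            [[_CODE[c] for c in s] for s in self.seqs], dtype=np.uint8
        )

    def subset(self, indices: list[int]) -> "Alignment":
        return Alignment(
            ids=[self.ids[i] for i in indices],
            species=[self.species[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
        )

    def records_for_species(self, species: str) -> list[int]:
        return [i for i, sp in enumerate(self.species) if sp == species]


def read_alignment(path: str | Path, species_map: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA; description line ``accession|species``."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"empty or non-FASTA file: {path}")
    ids, species, seqs = [], [], []
    for rec in records:
        name = rec.id
        if "|" in name:
            acc, sp = name.split("|", 1)
        else:
            acc = name
            sp = (species_map or {}).get(acc, acc)
        ids.append(acc)
        species.append(sp)
        seqs.append(str(rec.seq))
    return Alignment(ids=ids, species=species, seqs=seqs)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column (accession<TAB>species) mapping for bare-accession FASTA."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        out[parts[0].strip()] = parts[1].strip()
    return out


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{acc}|{sp}", description="")
        for acc, sp, s in zip(aln.ids, aln.species, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
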