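"""Genome sequences and FASTA input/output.

Coordinates are 0-based, half-open everywhere in this package.  Minus-strand
features are always reported in forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One named chromosome: an uppercase nucleotide string over {A,C,G,T,N}.

    Lowercase (soft-masked) input is uppercased at construction; masking is
    ignored.  Any other character is rejected.
    """

    name: str
    seq: str

    def __post_init__(self) -> None:
        upper = self.seq.upper()
        bad = set(upper) - VALID_BASES
        if bad:
            raise ValueError(
                f"chromosome {self.name!r} contains invalid characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "seq", upper)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


class Genome:
    """An ordered collection of chromosomes with name lookup."""

    def __init__(self, chroms: Iterable[GenomeSequence]):
        self.chroms: dict[str, GenomeSequence] = {}
        for c in chroms:
            if c.name in self.chroms:
                raise ValueError(f"duplicate chromosome name {c.name!r}")
            self.chroms[c.name] = c

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self.chroms.values())

    def __getitem__(self, name: str) -> GenomeSequence:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def names(self) -> list[str]:
        return list(self.chroms)


def read_fasta(path: str | Path) -> Genome:
    """Load a (possibly multi-record, line-wrapped) FASTA file."""
    records = [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(c.seq), id=c.name, description="") for c in genome]
    SeqIO.write(recs, str(path), "fasta")
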