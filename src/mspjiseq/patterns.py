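"""IUPAC degenerate-pattern scanning and CNNR site classification.

MspJI recognizes 5-methylcytosine in the CNNR context (R = A or G).  A
recognition site is *symmetric* when both strands carry a methylatable CNNR
whose cytosines base-pair within a few bases of each other; such paired sites
release defined two-way cleavage fragments.  Seven degenerate strings describe
the symmetric site categories, each tied to a signed offset ``d`` between the
plus-strand and minus-strand methylcytosines (d = minus C position − plus C
position, forward coordinates):

=========  ===  =================
pattern     d   two-way fragment
=========  ===  =================
YNCGNR     +1   32 bp (CG)
YCHGR      +2   31 bp (CHG)
CHHG       +3   30 bp
CYHAG      +4   29 bp
CHYAHG     +5   28 bp
TDDGCHHA   −1   34 bp
TDDGNCHHA  −2   35 bp
=========  ===  =================

The fragment length obeys L = 33 − d (see :mod:`mspjiseq.digestion`).

A genome letter ``N`` (unsequenced base) matches *no* pattern code, including
the pattern code ``N``: sites are never called on unsequenced bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .genome import Genome, GenomeSequence, revcomp

# Standard IUPAC nucleotide codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CNNR = "CNNR"

Strand = Literal["+", "-"]
Context = Literal["CG", "CHG", "CHH"]


def expand_code(code: str) -> frozenset[str]:
    """Concrete base set for one IUPAC symbol (e.g. R -> {A, G})."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol: {code!r}") from None


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of a degenerate pattern (H <-> D, R <-> Y, ...)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePattern:
    """A string of IUPAC codes used for exact degenerate matching."""

    text: str

    def __post_init__(self) -> None:
        text = self.text.upper()
        for ch in text:
            if ch not in IUPAC_CODES:
                raise ValueError(f"unknown IUPAC symbol: {ch!r}")
        object.__setattr__(self, "text", text)

    def __len__(self) -> int:
        return len(self.text)

    @property
    def length(self) -> int:
        return len(self.text)

    def to_regex(self) -> re.Pattern[str]:
        # Lookahead so overlapping matches are all reported.  Character
        # classes contain concrete bases only, so genome N never matches.
        body = "".join(f"[{''.join(sorted(IUPAC_CODES[c]))}]" for c in self.text)
        return re.compile(f"(?=({body}))")


def matches(window: str, pattern: DegeneratePattern | str) -> bool:
    """True iff every base of *window* is in the pattern code's base set.

    Any N in the window makes the match fail.  Window and pattern must have
    equal length.
    """
    pat = pattern.text if isinstance(pattern, DegeneratePattern) else pattern.upper()
    if len(window) != len(pat):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pat)}"
        )
    for base, code in zip(window.upper(), pat):
        if base not in IUPAC_CODES[code]:
            return False
    return True


def scan_sites(
    genome: Genome | GenomeSequence,
    pattern: DegeneratePattern | str,
    strands: Literal["both", "forward"] = "both",
) -> list[tuple[str, int, Strand]]:
    """All match start positions of *pattern* in *genome*.

    Positions are 0-based coordinates of the leftmost matched base in forward
    coordinates for both strands; minus-strand matches are evaluated on the
    reverse complement.  Overlapping matches are all reported.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern(pattern)
    if isinstance(genome, GenomeSequence):
        genome = Genome([genome])
    rx = pattern.to_regex()
    plen = len(pattern)
    out: list[tuple[str, int, Strand]] = []
    for chrom in genome:
        for m in rx.finditer(chrom.seq):
            out.append((chrom.name, m.start(), "+"))
        if strands == "both":
            rc = revcomp(chrom.seq)
            L = len(chrom)
            rev = sorted(L - m.start() - plen for m in rx.finditer(rc))
            out.extend((chrom.name, pos, "-") for pos in rev)
    return out


def classify_context(
    chrom: GenomeSequence, pos: int, strand: Strand
) -> tuple[Context, bool]:
    """Plant methylation context of the cytosine at (pos, strand).

    Returns (context, well_defined).  CG if the next base 3' on that strand
    is G; else CHG if the base after next is G; else CHH.  If either
    downstream base is N the context is undefined and reported as CHH with
    well_defined=False.
    """
    seq = chrom.seq
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at {pos}+ is {seq[pos]!r}, not C")
        if pos + 2 >= len(seq):
            raise ValueError(f"no two downstream bases after {pos}+")
        nxt, nxt2 = seq[pos + 1], seq[pos + 2]
    else:
        if seq[pos] != "G":
            raise ValueError(f"base at {pos}- is {revcomp(seq[pos])!r}, not C")
        if pos - 2 < 0:
            raise ValueError(f"no two downstream bases before {pos}-")
        nxt, nxt2 = revcomp(seq[pos - 1]), revcomp(seq[pos - 2])
    if "N" in (nxt, nxt2):
        return "CHH", False
    if nxt == "G":
        return "CG", True
    if nxt2 == "G":
        return "CHG", True
    return "CHH", True


@dataclass(frozen=True)
class CategoryDef:
    """One symmetric Table-1 category."""

    pattern: str
    d: int  # minus-strand C position − plus-strand C position
    plus_c: int  # index of the plus-strand C within the pattern
    fragment_length: int  # 33 − d

    @property
    def minus_c(self) -> int:
        return self.plus_c + self.d


#: The seven symmetric categories, in classification precedence order
#: (longest pattern first; ties broken by d; first match wins).
CATEGORIES: tuple[CategoryDef, ...] = (
    CategoryDef("TDDGNCHHA", -2, 5, 35),
    CategoryDef("TDDGCHHA", -1, 4, 34),
    CategoryDef("CHYAHG", 5, 0, 28),
    CategoryDef("CYHAG", 4, 0, 29),
    CategoryDef("YNCGNR", 1, 2, 32),
    CategoryDef("YCHGR", 2, 1, 31),
    CategoryDef("CHHG", 3, 0, 30),
)

CATEGORY_BY_NAME: dict[str, CategoryDef] = {c.pattern: c for c in CATEGORIES}

#: Table-1 row order (by fragment length 32..35).
CATEGORY_TABLE_ORDER: tuple[str, ...] = (
    "YNCGNR",
    "YCHGR",
    "CHHG",
    "CYHAG",
    "CHYAHG",
    "TDDGCHHA",
    "TDDGNCHHA",
)

ASYMMETRIC = "asymmetric"


@dataclass(frozen=True)
class CnnrLocus:
    """One recognized CNNR occurrence: the position of its (methylatable) C.

    ``pos`` is the 0-based forward coordinate of the C itself (for a
    minus-strand locus this is the coordinate of the G on the forward
    strand).  ``partner_offset_d`` is the signed offset to the partner C on
    the opposite strand for symmetric loci (None for asymmetric).
    """

    chrom: str
    pos: int
    strand: Strand
    context: Context
    category: str = ASYMMETRIC
    partner_offset_d: Optional[int] = None

    @property
    def is_symmetric(self) -> bool:
        return self.category != ASYMMETRIC

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def _is_cnnr(seq: str, pos: int, strand: Strand) -> bool:
    """Does the C at (pos, strand) sit in a CNNR context?"""
    if strand == "+":
        if pos + 3 >= len(seq):
            return False
        return matches(seq[pos : pos + 4], CNNR)
    if pos - 3 < 0:
        return False
    return matches(revcomp(seq[pos - 3 : pos + 1]), CNNR)


def classify_symmetric_category(
    chrom: GenomeSequence, pos: int, strand: Strand
) -> tuple[str, Optional[int]]:
    """Table-1 category of the CNNR locus at (pos, strand).

    Each category pattern is tested anchored so that the locus C occupies the
    category's plus-strand C position (for a plus locus) or its minus-strand
    partner position (for a minus locus).  Returns (category,
    partner_offset_d); no match, or a window extending past the chromosome
    end, yields ("asymmetric", None).  Precedence: longest pattern first,
    first match wins.
    """
    seq = chrom.seq
    if not _is_cnnr(seq, pos, strand):
        raise ValueError(f"({pos}, {strand}) is not a CNNR locus on {chrom.name}")
    for cat in CATEGORIES:
        anchor = cat.plus_c if strand == "+" else cat.minus_c
        start = pos - anchor
        end = start + len(cat.pattern)
        if start < 0 or end > len(seq):
            continue
        if matches(seq[start:end], cat.pattern):
            d = cat.d if strand == "+" else -cat.d
            return cat.pattern, d
    return ASYMMETRIC, None


def scan_cnnr_loci(
    genome: Genome | GenomeSequence, strands: Literal["both", "forward"] = "both"
) -> list[CnnrLocus]:
    """All CNNR loci in the genome, classified by context and category.

    Loci are keyed by the position of the C itself (a minus-strand CNNR match
    over forward interval [s, s+4) has its C at s+3).
    """
    if isinstance(genome, GenomeSequence):
        genome = Genome([genome])
    loci: list[CnnrLocus] = []
    for chrom in genome:
        chrom_hits: list[tuple[int, Strand]] = []
        for _, s, strand in scan_sites(chrom, CNNR, strands):
            pos = s if strand == "+" else s + 3
            chrom_hits.append((pos, strand))
        chrom_hits.sort()
        for pos, strand in chrom_hits:
            context, _ = classify_context(chrom, pos, strand)
            category, d = classify_symmetric_category(chrom, pos, strand)
            loci.append(CnnrLocus(chrom.name, pos, strand, context, category, d))
    return loci


def loci_to_bed(loci: Iterable[CnnrLocus]) -> list[str]:
    """6-column BED lines: chrom, start, end, category, d, strand."""
    lines = []
    for l in loci:
        d = "." if l.partner_offset_d is None else str(l.partner_offset_d)
        lines.append(
            f"{l.chrom}\t{l.pos}\t{l.pos + 1}\t{l.category}\t{d}\t{l.strand}"
        )
    return lines


def read_pattern_config(path: str) -> dict[str, DegeneratePattern]:
    """Read a name<TAB>pattern text config."""
    out: dict[str, DegeneratePattern] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, pat = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{i}: expected name<TAB>pattern") from None
            out[name] = DegeneratePattern(pat)
    return out
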