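"""The MspJI cut model and cleavage-scenario engine.

MspJI bound at a methylated C cuts both strands on the 3' side of the mC at
fixed distances: after the 12th nucleotide on the mC strand and after the
16th on the opposite strand, leaving a four-base 5' overhang.  In 0-based
half-open coordinates a plus-strand mC at ``p`` produces cut coordinates
``p+13`` (mC strand) and ``p+17`` (opposite strand); a minus-strand mC at
``q`` mirrors leftward to ``q-12`` and ``q-16``.

Because library end-repair fills in the 5' overhangs, the double-stranded
insert that is actually sequenced spans from outer cut to outer cut: the
product released between two neighbouring double-strand breaks is
``[left_break_min, right_break_max)``, each break contributing its 4-base
overhang to both flanking products.  For a two-way pair (plus mC at p, minus
mC at q, d = q - p) this gives span ``[q-16, p+17)`` and the length law
``L = 33 - d``.

Cleavage around two neighbouring methylated sites falls into six scenarios:

* A - same strand, >= 12 bp apart: independent cuts, one-way products.
* B - same strand, < 12 bp apart: competing cleavage, only a cut terminus.
* C - opposite strands cutting toward each other, d >= 29 bp: a released
  middle product with no recognition site.
* D - toward each other, 16 <= d <= 28: competing cleavage, terminus only.
* E - toward each other, 1 <= d <= 15: two-way cleavage, an 18-32 bp
  fragment containing both recognition sites.
* F - opposite strands cutting away from each other (minus site left of the
  plus site): two-way cleavage, >= 34 bp fragment containing both sites.

Neighbour pairs are resolved left to right in outer-cut order.  A candidate
product additionally survives only if no *other* methylated site's break
window lands in its interior; products lost this way are recorded as
competing-cleavage casualties, mirroring the unpredictability of competing
cleavage among densely methylated sites.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .genome import Genome, GenomeSequence, revcomp
from .patterns import (
    CATEGORY_BY_NAME,
    CATEGORY_TABLE_ORDER,
    CNNR,
    CnnrLocus,
    DegeneratePattern,
    classify_context,
    classify_symmetric_category,
    scan_cnnr_loci,
)

Scenario = Literal["A", "B", "C", "D", "E", "F"]

OVERHANG = 4
NEAR_OFFSET = 13  # cut coordinate offset on the mC strand (after N12)
FAR_OFFSET = 17  # cut coordinate offset on the opposite strand (after N16)


@dataclass(frozen=True)
class CutPair:
    """One double-strand break: near (N12) and far (N16) cut coordinates."""

    chrom: str
    near_cut: int
    far_cut: int
    overhang: int = OVERHANG

    def __post_init__(self) -> None:
        if abs(self.far_cut - self.near_cut) != self.overhang:
            raise ValueError("near/far cuts must be 4 bases apart")

    @property
    def window(self) -> tuple[int, int]:
        """Break window (lo, hi): the 4-base staggered-cut region."""
        lo, hi = sorted((self.near_cut, self.far_cut))
        return lo, hi


def cut_pair(
    locus: CnnrLocus, chrom_length: int, state: "MethylationState | None" = None
) -> Optional[CutPair]:
    """Cut coordinates for one methylated locus, or None if out of bounds."""
    if state is not None and not state.is_methylated(locus):
        raise ValueError(f"locus {locus.key()} is not methylated in this state")
    if locus.strand == "+":
        near, far = locus.pos + NEAR_OFFSET, locus.pos + FAR_OFFSET
        if far > chrom_length:
            return None
    else:
        near, far = locus.pos - NEAR_OFFSET + 1, locus.pos - FAR_OFFSET + 1
        if far < 0:
            return None
    return CutPair(locus.chrom, near, far)


@dataclass
class MethylationState:
    """Which CNNR cytosines are methylated.

    ``all_cnnr`` methylates every CNNR cytosine (the all-methylated
    assumption used for whole-genome digestion simulation); ``explicit``
    takes a set of (chrom, pos, strand) keys that must be CNNR loci.
    """

    mode: Literal["all_cnnr", "explicit"] = "all_cnnr"
    methylated: frozenset[tuple[str, int, str]] = frozenset()

    @classmethod
    def all_sites(cls) -> "MethylationState":
        return cls(mode="all_cnnr")

    @classmethod
    def from_loci(cls, loci: Iterable[CnnrLocus]) -> "MethylationState":
        return cls(mode="explicit", methylated=frozenset(l.key() for l in loci))

    @classmethod
    def from_keys(
        cls, keys: Iterable[tuple[str, int, str]]
    ) -> "MethylationState":
        return cls(mode="explicit", methylated=frozenset(keys))

    def is_methylated(self, locus: CnnrLocus) -> bool:
        return self.mode == "all_cnnr" or locus.key() in self.methylated

    def loci_for(self, genome: Genome) -> list[CnnrLocus]:
        """The methylated loci of this state, classified against *genome*."""
        all_loci = scan_cnnr_loci(genome)
        if self.mode == "all_cnnr":
            return all_loci
        by_key = {l.key(): l for l in all_loci}
        out = []
        for key in sorted(self.methylated):
            if key not in by_key:
                raise ValueError(
                    f"explicit methylated position {key} is not a CNNR locus"
                )
            out.append(by_key[key])
        return out


@dataclass(frozen=True)
class Fragment:
    """An end-repaired digestion product (outer-cut to outer-cut span)."""

    chrom: str
    start: int
    end: int
    scenario: Scenario
    loci_inside: tuple[CnnrLocus, ...] = ()
    category: Optional[str] = None  # Table-1 category for symmetric two-way

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, chrom: GenomeSequence) -> str:
        return chrom.seq[self.start : self.end]


@dataclass(frozen=True)
class TerminusEvent:
    """A competing-cleavage pair (scenario B or D): a cut terminus only."""

    chrom: str
    scenario: Scenario
    locus_a: CnnrLocus
    locus_b: CnnrLocus


@dataclass
class DigestResult:
    fragments: list[Fragment] = field(default_factory=list)
    termini: list[TerminusEvent] = field(default_factory=list)
    destroyed: list[Fragment] = field(default_factory=list)
    boundary_lost: list[CnnrLocus] = field(default_factory=list)

    def two_way(self) -> list[Fragment]:
        return [f for f in self.fragments if f.scenario in ("E", "F")]


@dataclass(frozen=True)
class SizeSelection:
    """Inclusive fragment-length window retained from the gel."""

    min_len: int = 28
    max_len: int = 35

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")

    def keeps(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def expected_fragment_length(d: int) -> int:
    """Two-way fragment length for paired-C offset d: L = 33 - d."""
    if d == 0:
        raise ValueError("d = 0 is impossible: a C cannot base-pair with a C")
    if not -2 <= d <= 15:
        raise ValueError(f"d = {d} outside the two-way range [-2, 15]")
    return 33 - d


def resolve_scenario(locus_a: CnnrLocus, locus_b: CnnrLocus) -> Scenario:
    """Cleavage scenario for two nearest methylated neighbours."""
    if locus_a.key() == locus_b.key():
        raise ValueError("identical locus passed twice")
    if locus_a.strand == locus_b.strand:
        return "A" if abs(locus_a.pos - locus_b.pos) >= 12 else "B"
    plus, minus = (
        (locus_a, locus_b) if locus_a.strand == "+" else (locus_b, locus_a)
    )
    d = minus.pos - plus.pos
    if d <= -1:
        return "F"
    if 1 <= d <= 15:
        return "E"
    if 16 <= d <= 28:
        return "D"
    return "C"


def _pair_category(
    plus: CnnrLocus, minus: CnnrLocus
) -> Optional[str]:
    """Table-1 category when this plus/minus pair is the classified partner."""
    if plus.is_symmetric and plus.partner_offset_d == minus.pos - plus.pos:
        return plus.category
    return None


def digest(
    genome: Genome,
    state: MethylationState,
    size: Optional[SizeSelection] = None,
) -> DigestResult:
    """Digest *genome* under *state*; optionally size-select the output.

    Methylated loci are sorted by outer-cut coordinate per chromosome;
    adjacent pairs are resolved into scenarios A-F; A/C/E/F pairs yield the
    product between their breaks, B/D pairs only a terminus.  A candidate
    product invaded by any other methylated locus's break window is recorded
    under ``destroyed`` (competing cleavage), not emitted.
    """
    loci = state.loci_for(genome)
    result = DigestResult()
    for chrom_name in sorted(genome.names()):
        chrom = genome[chrom_name]
        events = []
        for locus in loci:
            if locus.chrom != chrom_name:
                continue
            cp = cut_pair(locus, len(chrom))
            if cp is None:
                result.boundary_lost.append(locus)
                continue
            lo, hi = cp.window
            far = cp.far_cut
            events.append((far, locus.pos, locus, lo, hi))
        events.sort(key=lambda e: (e[0], e[1], e[2].strand))
        positions = sorted(e[2].pos for e in events)
        pos_to_loci: dict[int, list[CnnrLocus]] = {}
        for e in events:
            pos_to_loci.setdefault(e[2].pos, []).append(e[2])
        lows = sorted((e[3], e[4], e[2].key()) for e in events)
        low_vals = [w[0] for w in lows]

        def invaded(start: int, end: int, own: set) -> bool:
            # any other break window (lo, hi) with lo < end and hi > start
            i = bisect_left(low_vals, start - OVERHANG)
            while i < len(lows) and lows[i][0] < end:
                lo, hi, key = lows[i]
                if hi > start and key not in own:
                    return True
                i += 1
            return False

        def contained(start: int, end: int) -> tuple[CnnrLocus, ...]:
            i, j = bisect_left(positions, start), bisect_right(positions, end - 1)
            out: list[CnnrLocus] = []
            for p in sorted(set(positions[i:j])):
                out.extend(pos_to_loci[p])
            return tuple(out)

        for i in range(len(events) - 1):
            _, _, a, a_lo, a_hi = events[i]
            _, _, b, b_lo, b_hi = events[i + 1]
            scen = resolve_scenario(a, b)
            if scen in ("B", "D"):
                result.termini.append(TerminusEvent(chrom_name, scen, a, b))
                continue
            (lo1, hi1), (lo2, hi2) = sorted(((a_lo, a_hi), (b_lo, b_hi)))
            start, end = lo1, hi2
            if end <= start:
                continue
            category = None
            if scen in ("E", "F"):
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                category = _pair_category(plus, minus)
            frag = Fragment(
                chrom_name, start, end, scen, contained(start, end), category
            )
            if invaded(start, end, {a.key(), b.key()}):
                result.destroyed.append(frag)
            else:
                result.fragments.append(frag)
    result.fragments.sort(key=lambda f: (f.chrom, f.start, f.end))
    if size is not None:
        result.fragments = size_select(result.fragments, size)
    return result


def size_select(
    fragments: Sequence[Fragment], sel: SizeSelection = SizeSelection()
) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len (inclusive)."""
    return [f for f in fragments if sel.keeps(f.length)]


@dataclass
class CensusResult:
    """Per-category symmetric-site census of a genome."""

    counts: dict[str, int]
    cytosines_in_sites: int
    total_cytosines: int
    generation_rate: float

    def to_rows(self) -> list[tuple[str, int, int]]:
        return [
            (name, CATEGORY_BY_NAME[name].fragment_length, self.counts[name])
            for name in CATEGORY_TABLE_ORDER
        ]


def census(genome: Genome) -> CensusResult:
    """Count forward-strand matches of the seven symmetric-site patterns.

    Each match is one symmetric locus carrying two methylatable cytosines;
    the generation rate is the fraction of all genomic cytosines (forward C
    plus G, i.e. both strands) recoverable in the size-selected two-way
    band under the all-methylated assumption.
    """
    counts = {name: 0 for name in CATEGORY_TABLE_ORDER}
    total_c = 0
    for chrom in genome:
        total_c += chrom.seq.count("C") + chrom.seq.count("G")
        for name in CATEGORY_TABLE_ORDER:
            rx = DegeneratePattern(name).to_regex()
            counts[name] += sum(1 for _ in rx.finditer(chrom.seq))
    in_sites = 2 * sum(counts.values())
    rate = in_sites / total_c if total_c else 0.0
    if total_c == 0:
        warnings.warn("genome contains no cytosines; generation rate set to 0")
    return CensusResult(counts, in_sites, total_c, rate)


def cnnr_fraction(genome: Genome) -> float:
    """Fraction of all cytosines (both strands) lying in CNNR context."""
    rx = DegeneratePattern(CNNR).to_regex()
    n_loci = 0
    n_cyt = 0
    for chrom in genome:
        n_cyt += chrom.seq.count("C") + chrom.seq.count("G")
        n_loci += sum(1 for _ in rx.finditer(chrom.seq))
        n_loci += sum(1 for _ in rx.finditer(revcomp(chrom.seq)))
    if n_cyt == 0:
        warnings.warn("genome contains no cytosines; CNNR fraction set to 0")
        return 0.0
    return n_loci / n_cyt


def count_occurrences(genome: Genome, s: str) -> int:
    """Overlapping occurrence count of substring *s* on the forward strand."""
    total = 0
    for chrom in genome:
        start = 0
        while True:
            i = chrom.seq.find(s, start)
            if i == -1:
                break
            total += 1
            start = i + 1
    return total


def joint_occurrences(genome: Genome, s: str) -> int:
    """Occurrences of *s* or its reverse complement, genome-wide."""
    rc = revcomp(s)
    n = count_occurrences(genome, s)
    if rc != s:
        n += count_occurrences(genome, rc)
    return n


@dataclass
class MappabilityResult:
    total_fraction: float
    unique_fraction: float
    per_length: dict[int, tuple[float, float]]
    n_sampled: int
    n_excluded_n: int


def simulate_fragment_mappability(
    genome: Genome,
    lengths: Sequence[int] = tuple(range(28, 36)),
    n_per_length: int = 1000,
    seed: int = 0,
) -> MappabilityResult:
    """Sample random genomic substrings and re-locate them exactly.

    Every sampled substring occurs in the genome by construction, so the
    total mappable fraction only falls below 1 through N-containing draws
    (which are excluded from numerator and denominator).  A substring is
    *uniquely* mappable iff it and its reverse complement jointly occur
    exactly once genome-wide.  This approximates the original aligner-based
    re-mapping simulation with exact string matching.
    """
    if n_per_length < 1:
        raise ValueError("n_per_length must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome]
    weights = np.array([len(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    per_length: dict[int, tuple[float, float]] = {}
    tot_mapped = tot_unique = tot_used = excluded = 0
    for L in lengths:
        usable = [c for c in chroms if len(c) >= L]
        if not usable:
            warnings.warn(f"no chromosome of length >= {L}; skipped")
            continue
        mapped = unique = used = 0
        for _ in range(n_per_length):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            if len(chrom) < L:
                continue
            start = int(rng.integers(0, len(chrom) - L + 1))
            s = chrom.seq[start : start + L]
            if "N" in s:
                excluded += 1
                continue
            used += 1
            mapped += 1  # occurs by construction
            if joint_occurrences(genome, s) == 1:
                unique += 1
        if used:
            per_length[L] = (mapped / used, unique / used)
        tot_mapped += mapped
        tot_unique += unique
        tot_used += used
    total_frac = tot_mapped / tot_used if tot_used else 0.0
    unique_frac = tot_unique / tot_used if tot_used else 0.0
    return MappabilityResult(total_frac, unique_frac, per_length, tot_used, excluded)


def fragments_to_bed(fragments: Iterable[Fragment]) -> list[str]:
    """BED6+ lines: chrom, start, end, scenario:category, length, strand."""
    lines = []
    for f in fragments:
        name = f.scenario if f.category is None else f"{f.scenario}:{f.category}"
        lines.append(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{f.length}\t.")
    return lines
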