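"""Attribute mapped insert fragments to methylated CNNR loci.

The caller inverts the digestion geometry: a two-way insert spans
``[q-16, p+17)`` for a plus-strand mC at ``p`` and a minus-strand mC at
``q``, so for a mapped fragment ``[start, end)`` the candidate methylcytosines
sit at fixed offsets ``end-17`` (plus strand) and ``start+16`` (minus
strand).  A candidate is accepted iff the *reference* carries a CNNR at that
position and strand — surrounding reference sequence, not the read, decides,
which makes the call robust to sequencing errors.  An optional one-base
wobble re-tests the neighbouring positions, matching the enzyme's known
low-frequency cut wobble seen in 33-bp fragments.

Depth is counted per fragment: a two-way fragment supports both of its loci,
and duplicate fragments are not collapsed (fragment count is the methylation
signal).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .genome import Genome, GenomeSequence
from .patterns import (
    CnnrLocus,
    classify_context,
    classify_symmetric_category,
    _is_cnnr,
)

PLUS_C_FROM_END = 17  # plus-strand mC sits 17 bases left of the insert end
MINUS_C_FROM_START = 16  # minus-strand mC sits 16 bases right of the start


@dataclass(frozen=True)
class AlignedFragment:
    """A mapped (trimmed) read's inferred insert interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    multiplicity: int = 1
    positions: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.end <= self.start:
            raise ValueError("empty fragment interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MappingStats:
    n_clean: int = 0
    n_mapped: int = 0
    n_unique: int = 0
    n_unmapped: int = 0

    @property
    def mapping_rate(self) -> float:
        return self.n_mapped / self.n_clean if self.n_clean else 0.0

    @property
    def unique_rate(self) -> float:
        return self.n_unique / self.n_clean if self.n_clean else 0.0


@dataclass(frozen=True)
class SiteCall:
    """A called methylated locus with its supporting fragment count."""

    locus: CnnrLocus
    depth: int
    unique_only: bool = False


@dataclass(frozen=True)
class RegionMethylation:
    """Per-interval methylation summaries.

    ``read_density`` (fragments whose notarized locus falls in the interval)
    and ``mc_fraction`` (called loci / CNNR loci in the interval) are the two
    region-level "relative methylation" variants.
    """

    chrom: str
    start: int
    end: int
    read_density: int
    mc_fraction: float
    n_cnnr: int
    n_called: int
    zero_denominator: bool = False


def infer_fragments(
    sam_path: str | Path, reference: Genome
) -> tuple[list[AlignedFragment], MappingStats]:
    """Read SAM/BAM alignments into insert fragments.

    Multiplicity comes from the NH auxiliary tag when present, otherwise
    from the number of alignment records sharing a read name (both dialects
    of multi-mapper reporting).  Unmapped reads are counted, not returned.
    """
    import pysam

    stats = MappingStats()
    per_read: dict[str, list] = defaultdict(list)
    n_unmapped = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.reference_name not in reference:
                raise ValueError(
                    f"alignment chromosome {rec.reference_name!r} not in reference"
                )
            per_read[rec.query_name].append(rec.to_dict() | {
                "_chrom": rec.reference_name,
                "_start": rec.reference_start,
                "_end": rec.reference_end,
                "_strand": "-" if rec.is_reverse else "+",
                "_nh": rec.get_tag("NH") if rec.has_tag("NH") else None,
            })
    fragments: list[AlignedFragment] = []
    for name, recs in per_read.items():
        nh = recs[0]["_nh"]
        mult = int(nh) if nh is not None else len(recs)
        positions = tuple(
            (r["_chrom"], r["_start"], r["_end"], r["_strand"]) for r in recs
        )
        r0 = recs[0]
        fragments.append(
            AlignedFragment(
                r0["_chrom"], r0["_start"], r0["_end"], r0["_strand"], mult, positions
            )
        )
    stats.n_clean = len(per_read) + n_unmapped
    stats.n_mapped = len(per_read)
    stats.n_unique = sum(1 for f in fragments if f.multiplicity == 1)
    stats.n_unmapped = n_unmapped
    return fragments, stats


def _locus_at(
    chrom: GenomeSequence, pos: int, strand: str
) -> Optional[CnnrLocus]:
    if strand == "+" and not (0 <= pos <= len(chrom) - 4):
        return None
    if strand == "-" and not (3 <= pos < len(chrom)):
        return None
    if not _is_cnnr(chrom.seq, pos, strand):
        return None
    context, _ = classify_context(chrom, pos, strand)
    category, d = classify_symmetric_category(chrom, pos, strand)
    return CnnrLocus(chrom.name, pos, strand, context, category, d)


def notarize_cnnr(
    fragment: AlignedFragment, reference: Genome, wobble: int = 0
) -> list[CnnrLocus]:
    """CNNR loci at the cut-model offsets of a mapped fragment.

    Tests a plus-strand C at ``end - 17`` and a minus-strand C at
    ``start + 16`` against the reference; with ``wobble=1`` the positions
    one base either side are also tried when the exact offset fails.
    """
    if wobble not in (0, 1):
        raise ValueError("wobble must be 0 or 1")
    if fragment.chrom not in reference:
        raise ValueError(f"fragment chromosome {fragment.chrom!r} not in reference")
    chrom = reference[fragment.chrom]
    if fragment.start < 0 or fragment.end > len(chrom):
        raise ValueError("fragment outside reference")
    out: list[CnnrLocus] = []
    for anchor, strand in (
        (fragment.end - PLUS_C_FROM_END, "+"),
        (fragment.start + MINUS_C_FROM_START, "-"),
    ):
        locus = _locus_at(chrom, anchor, strand)
        if locus is None and wobble:
            for delta in (-1, 1):
                locus = _locus_at(chrom, anchor + delta, strand)
                if locus is not None:
                    break
        if locus is not None:
            out.append(locus)
    return out


def call_sites(
    fragments: Sequence[AlignedFragment],
    reference: Genome,
    unique_only: bool = False,
    wobble: int = 0,
) -> list[SiteCall]:
    """Aggregate notarized loci over fragments into depth-carrying calls."""
    depth: Counter = Counter()
    loci: dict[tuple, CnnrLocus] = {}
    for frag in fragments:
        if unique_only and frag.multiplicity > 1:
            continue
        for locus in notarize_cnnr(frag, reference, wobble):
            depth[locus.key()] += 1
            loci[locus.key()] = locus
    return [
        SiteCall(loci[key], depth[key], unique_only)
        for key in sorted(depth)
    ]


def annotate_multimappers(
    fragments: Sequence[AlignedFragment],
    regions: dict[str, list[tuple[str, int, int]]],
    n_resample: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean per-region-class read counts under multi-mapper resampling.

    Each multiply-mapped fragment is assigned to one of its reported
    positions uniformly at random; the assignment is repeated ``n_resample``
    times and per-class counts are averaged.  Positions outside every region
    class count toward ``"intergenic"``.  Mass is conserved: the summed mean
    counts equal the number of fragments.
    """
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    labels = sorted(regions)
    for label in labels:
        for chrom, start, end in regions[label]:
            trees[chrom].addi(start, end, label)

    def label_of(chrom: str, start: int, end: int) -> str:
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        if not hits:
            return "intergenic"
        return min(h.data for h in hits)  # deterministic tie-break

    rng = np.random.default_rng(seed)
    totals: Counter = Counter()
    for frag in fragments:
        pos_list = frag.positions or ((frag.chrom, frag.start, frag.end, frag.strand),)
        if len(pos_list) == 0:
            raise ValueError("fragment with empty position list")
        pos_labels = [label_of(c, s, e) for c, s, e, _ in pos_list]
        if len(pos_labels) == 1:
            totals[pos_labels[0]] += n_resample
        else:
            draws = rng.integers(0, len(pos_labels), size=n_resample)
            for di, cnt in zip(*np.unique(draws, return_counts=True)):
                totals[pos_labels[int(di)]] += int(cnt)
    return {label: totals[label] / n_resample for label in totals}


def windows(genome: Genome, width: int) -> list[tuple[str, int, int]]:
    """Tile every chromosome into fixed-width intervals (last one clipped)."""
    out = []
    for chrom in genome:
        for start in range(0, len(chrom), width):
            out.append((chrom.name, start, min(start + width, len(chrom))))
    return out


class LocusIndex:
    """Sorted per-(chrom) position index over a locus collection."""

    def __init__(self, loci: Iterable[CnnrLocus]):
        self._by_chrom: dict[str, list[int]] = defaultdict(list)
        for l in loci:
            self._by_chrom[l.chrom].append(l.pos)
        for positions in self._by_chrom.values():
            positions.sort()

    def count_in(self, chrom: str, start: int, end: int) -> int:
        positions = self._by_chrom.get(chrom, [])
        return bisect_left(positions, end) - bisect_left(positions, start)


def region_methylation(
    site_calls: Sequence[SiteCall],
    fragments: Sequence[AlignedFragment],
    intervals: Sequence[tuple[str, int, int]],
    reference: Genome,
    cnnr_index: Optional[LocusIndex] = None,
    wobble: int = 0,
) -> list[RegionMethylation]:
    """Per-interval read density and called/total CNNR fraction."""
    from .patterns import scan_cnnr_loci

    if cnnr_index is None:
        cnnr_index = LocusIndex(scan_cnnr_loci(reference))
    called_index = LocusIndex(c.locus for c in site_calls)
    frag_locus_pos: dict[str, list[int]] = defaultdict(list)
    for frag in fragments:
        for locus in notarize_cnnr(frag, reference, wobble):
            frag_locus_pos[frag.chrom].append(locus.pos)
            break  # one interval assignment per fragment
    for v in frag_locus_pos.values():
        v.sort()
    out = []
    for chrom, start, end in intervals:
        if chrom in reference and end > len(reference[chrom]):
            warnings.warn(f"interval {chrom}:{start}-{end} clipped to chromosome end")
            end = len(reference[chrom])
        positions = frag_locus_pos.get(chrom, [])
        density = bisect_left(positions, end) - bisect_left(positions, start)
        n_cnnr = cnnr_index.count_in(chrom, start, end)
        n_called = called_index.count_in(chrom, start, end)
        if n_cnnr == 0:
            out.append(RegionMethylation(chrom, start, end, density, 0.0, 0, n_called, True))
        else:
            out.append(
                RegionMethylation(
                    chrom, start, end, density, n_called / n_cnnr, n_cnnr, n_called
                )
            )
    return out


def fragment_length_spectrum(
    fragments: Sequence[AlignedFragment | object],
) -> dict[int | str, int]:
    """Length histogram over the reported 26-39 bp insert range."""
    spectrum: dict[int | str, int] = {L: 0 for L in range(26, 40)}
    spectrum["other"] = 0
    for frag in fragments:
        L = frag.length
        if L in spectrum:
            spectrum[L] += 1
        else:
            spectrum["other"] += 1
    return spectrum


def position_frequency_matrix(
    fragments: Sequence[AlignedFragment],
    reference: Genome,
    length: int,
    n_sample: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-position A/C/G/T frequencies of sampled fragments of one length.

    Returns a (4, length) matrix in A,C,G,T row order; sequence-logo
    rendering is left to the caller.  When fewer than ``n_sample`` fragments
    exist they are all used without resampling.
    """
    pool = [f for f in fragments if f.length == length]
    if not pool:
        raise ValueError(f"no fragments of length {length}")
    if len(pool) > n_sample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n_sample, replace=False)
        pool = [pool[i] for i in idx]
    counts = np.zeros((4, length))
    row = {"A": 0, "C": 1, "G": 2, "T": 3}
    used = 0
    for frag in pool:
        seq = reference[frag.chrom].seq[frag.start : frag.end]
        if "N" in seq:
            continue
        used += 1
        for i, base in enumerate(seq):
            counts[row[base], i] += 1
    if used == 0:
        raise ValueError("all sampled fragments contain N")
    return counts / used
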