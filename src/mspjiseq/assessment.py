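"""Assessment statistics: WGBS comparison, repeatability, methylome profiling.

The enzyme-enrichment call set is validated against bisulfite-style per-site
counts: sites are called methylated either by a one-sided binomial test
against the bisulfite error rate with Benjamini-Hochberg control (the
Lister-style procedure) or by the looser any-supporting-read rule.
Specificity and sensitivity are computed on symmetric CG sites inside
enriched peak regions whose 32-bp two-way fragments are unique in the
genome; repeatability is the Pearson correlation of per-peak statistics
between replicates.  Metagene profiles average region-level methylation over
20 equal body bins plus 1-kb flanks in 100-bp bins.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .caller import LocusIndex, SiteCall
from .digestion import joint_occurrences
from .genome import Genome
from .patterns import CnnrLocus

WGBS_COLUMNS = ["chrom", "pos", "strand", "methylated_reads", "total_reads"]


def read_wgbs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(WGBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"WGBS table missing columns: {sorted(missing)}")
    return df


def write_wgbs_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def wgbs_call(
    records: pd.DataFrame,
    error_rate: float = 0.01,
    fdr: float = 0.05,
    mode: Literal["binomial", "any_read"] = "binomial",
) -> set[tuple[str, int, str]]:
    """Methylated-site keys from per-site bisulfite counts.

    ``binomial``: one-sided test of methylated_reads out of total_reads
    against the error rate, Benjamini-Hochberg corrected across all tested
    (covered) sites.  ``any_read``: any site covered by at least one read
    supporting methylation.  Uncovered sites are untested.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    covered = records[records["total_reads"] > 0]
    keys = list(zip(covered["chrom"], covered["pos"], covered["strand"]))
    if mode == "any_read":
        mask = covered["methylated_reads"].to_numpy() >= 1
        return {k for k, m in zip(keys, mask) if m}
    if mode != "binomial":
        raise ValueError(f"unknown mode {mode!r}")
    if not covered.shape[0]:
        return set()
    k = covered["methylated_reads"].to_numpy()
    n = covered["total_reads"].to_numpy()
    pvals = stats.binom.sf(k - 1, n, error_rate)
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return {key for key, r in zip(keys, reject) if r}


def fragment_uniqueness(
    genome: Genome, locus: CnnrLocus, length: int = 32
) -> tuple[bool, bool]:
    """Is the two-way insert around a symmetric CGNR locus genome-unique?

    Returns (unique, in_bounds).  The 32-bp insert spans [p-15, p+17) for
    the plus-strand C at p (partner at p+1); a locus too close to the
    chromosome edge is reported as (False, False).
    """
    if locus.strand == "+":
        p = locus.pos
    else:
        if locus.partner_offset_d is None:
            raise ValueError("minus-strand locus without a partner offset")
        p = locus.pos + locus.partner_offset_d
    start, end = p + 17 - length, p + 17
    chrom = genome[locus.chrom]
    if start < 0 or end > len(chrom):
        return False, False
    s = chrom.seq[start:end]
    if "N" in s:
        return False, True
    return joint_occurrences(genome, s) == 1, True


@dataclass(frozen=True)
class PeakRegion:
    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty peak interval")


def read_bed(path: str | Path, source: str = "") -> list[PeakRegion]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            peaks.append(PeakRegion(fields[0], int(fields[1]), int(fields[2]), source))
    return peaks


def common_peaks(
    peaks_a: Sequence[PeakRegion], peaks_b: Sequence[PeakRegion]
) -> list[PeakRegion]:
    """Merged >= 1 bp intersections of two peak sets."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for a in peaks_a:
        for b in peaks_b:
            if a.chrom == b.chrom:
                lo, hi = max(a.start, b.start), min(a.end, b.end)
                if lo < hi:
                    by_chrom[a.chrom].append((lo, hi))
    out = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        merged = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out.extend(PeakRegion(chrom, lo, hi, "common") for lo, hi in merged)
    return out


def _in_peaks(locus: CnnrLocus, peaks: Sequence[PeakRegion]) -> bool:
    return any(
        p.chrom == locus.chrom and p.start <= locus.pos < p.end for p in peaks
    )


def restrict_calls(
    loci: Iterable[CnnrLocus],
    peaks: Sequence[PeakRegion],
    genome: Optional[Genome] = None,
    category: Optional[str] = "YNCGNR",
    require_unique: bool = True,
) -> set[tuple[str, int, str]]:
    """Keys of loci inside peaks, of one category, with unique 32-mers."""
    out = set()
    for locus in loci:
        if category is not None and locus.category != category:
            continue
        if peaks is not None and not _in_peaks(locus, peaks):
            continue
        if require_unique:
            if genome is None:
                raise ValueError("require_unique needs the genome")
            unique, _ = fragment_uniqueness(genome, locus)
            if not unique:
                continue
        out.add(locus.key())
    return out


def specificity_sensitivity(
    mspji_keys: set[tuple[str, int, str]],
    wgbs_keys: set[tuple[str, int, str]],
) -> tuple[Optional[float], Optional[float]]:
    """(specificity, sensitivity) of one call set against a reference set.

    Specificity = |shared| / |caller set|; sensitivity = |shared| /
    |reference set|.  Both sets should already be restricted to the same
    peaks/uniqueness universe (see :func:`restrict_calls`).  Empty sets give
    None with a warning.
    """
    shared = mspji_keys & wgbs_keys
    spec = sens = None
    if mspji_keys:
        spec = len(shared) / len(mspji_keys)
    else:
        warnings.warn("empty test call set: specificity undefined")
    if wgbs_keys:
        sens = len(shared) / len(wgbs_keys)
    else:
        warnings.warn("empty reference call set: sensitivity undefined")
    return spec, sens


def replicate_correlation(
    calls_rep1: Sequence[SiteCall],
    calls_rep2: Sequence[SiteCall],
    peaks: Sequence[PeakRegion],
    statistic: Literal["site_count", "depth"] = "site_count",
) -> float:
    """Pearson r of a per-peak statistic between two replicates."""
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks")

    def per_peak(calls: Sequence[SiteCall]) -> np.ndarray:
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for c in calls:
            by_chrom[c.locus.chrom].append((c.locus.pos, c.depth))
        for v in by_chrom.values():
            v.sort()
        vals = []
        for p in peaks:
            items = by_chrom.get(p.chrom, [])
            positions = [x[0] for x in items]
            i, j = bisect_left(positions, p.start), bisect_left(positions, p.end)
            if statistic == "site_count":
                vals.append(j - i)
            else:
                vals.append(sum(d for _, d in items[i:j]))
        return np.asarray(vals, dtype=float)

    x, y = per_peak(calls_rep1), per_peak(calls_rep2)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in a replicate vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class MetageneProfile:
    """Averaged methylation over scaled gene bodies and fixed flanks."""

    body_bins: np.ndarray  # 20 values, TSS side first
    upstream: np.ndarray  # 10 x 100 bp, outermost first
    downstream: np.ndarray  # 10 x 100 bp, TTS-proximal first
    n_regions: int
    context: Optional[str] = None


ValueFn = Callable[[str, int, int], float]


def mc_fraction_value_fn(
    site_calls: Sequence[SiteCall], cnnr_index: LocusIndex
) -> ValueFn:
    """Relative methylation as called / total CNNR loci in an interval."""
    called = LocusIndex(c.locus for c in site_calls)

    def fn(chrom: str, start: int, end: int) -> float:
        n = cnnr_index.count_in(chrom, start, end)
        if n == 0:
            return float("nan")
        return called.count_in(chrom, start, end) / n

    return fn


def density_value_fn(site_calls: Sequence[SiteCall]) -> ValueFn:
    """Relative methylation as depth-weighted calls per base."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in site_calls:
        by_chrom[c.locus.chrom].append((c.locus.pos, c.depth))
    for v in by_chrom.values():
        v.sort()

    def fn(chrom: str, start: int, end: int) -> float:
        if end <= start:
            return float("nan")
        items = by_chrom.get(chrom, [])
        positions = [x[0] for x in items]
        i, j = bisect_left(positions, start), bisect_left(positions, end)
        return sum(d for _, d in items[i:j]) / (end - start)

    return fn


def metagene_profile(
    regions: pd.DataFrame,
    value_fn: ValueFn,
    chrom_lengths: dict[str, int],
    bins: int = 20,
    flank: int = 1000,
    flank_bin: int = 100,
    context: Optional[str] = None,
) -> MetageneProfile:
    """Average a value function over scaled regions and fixed flanks.

    ``regions`` needs chrom/start/end/strand columns.  Each region is split
    into ``bins`` equal intervals (minus-strand regions reversed so bin 1 is
    the TSS side); flanks are binned at ``flank_bin`` bp and clipped at
    chromosome ends (clipped bins contribute NaN).  Regions shorter than
    ``bins`` bases are skipped with a warning.
    """
    n_flank = flank // flank_bin
    body_acc = []
    up_acc = []
    down_acc = []
    n_used = 0
    for r in regions.itertuples():
        length = r.end - r.start
        if length < bins:
            warnings.warn(f"region {r.chrom}:{r.start}-{r.end} shorter than {bins} bp; skipped")
            continue
        n_used += 1
        edges = [r.start + round(k * length / bins) for k in range(bins + 1)]
        body = [value_fn(r.chrom, edges[k], edges[k + 1]) for k in range(bins)]
        L = chrom_lengths[r.chrom]

        def flank_vals(anchor: int, direction: int) -> list[float]:
            # direction -1: bins to the left of anchor; +1: to the right
            vals = []
            for k in range(n_flank):
                if direction < 0:
                    lo, hi = anchor - (k + 1) * flank_bin, anchor - k * flank_bin
                else:
                    lo, hi = anchor + k * flank_bin, anchor + (k + 1) * flank_bin
                lo_c, hi_c = max(lo, 0), min(hi, L)
                vals.append(
                    value_fn(r.chrom, lo_c, hi_c) if hi_c > lo_c else float("nan")
                )
            return vals

        left = flank_vals(r.start, -1)  # innermost first
        right = flank_vals(r.end, +1)
        if r.strand == "-":
            body = body[::-1]
            up = right  # upstream of a minus-strand gene lies to the right
            down = left
        else:
            up = left
            down = right
        # upstream reported outermost-first, downstream TTS-proximal first
        up_acc.append(up[::-1])
        down_acc.append(down)
        body_acc.append(body)
    if n_used == 0:
        raise ValueError("no usable regions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        body = np.nanmean(np.array(body_acc, dtype=float), axis=0)
        up = np.nanmean(np.array(up_acc, dtype=float), axis=0)
        down = np.nanmean(np.array(down_acc, dtype=float), axis=0)
    return MetageneProfile(body, up, down, n_used, context)


def normalize_gene_methylation(
    genes: pd.DataFrame,
    value_fn: ValueFn,
    genome: Genome,
    promoter_len: int = 1000,
) -> pd.DataFrame:
    """Per-gene body and promoter methylation relative to the genome mean.

    The genome-wide mean relative methylation (the value function over each
    whole chromosome, length-weighted) scales every gene; promoters are
    ``promoter_len`` bases upstream of the TSS, strand-aware and clipped.
    """
    total = 0.0
    weight = 0.0
    for chrom in genome:
        v = value_fn(chrom.name, 0, len(chrom))
        if not np.isnan(v):
            total += v * len(chrom)
            weight += len(chrom)
    if weight == 0 or total == 0:
        raise ValueError("genome-wide mean methylation is zero; cannot normalize")
    genome_mean = total / weight
    rows = []
    for r in genes.itertuples():
        L = len(genome[r.chrom])
        body = value_fn(r.chrom, r.start, r.end)
        if r.strand == "-":
            plo, phi = r.end, min(r.end + promoter_len, L)
        else:
            plo, phi = max(r.start - promoter_len, 0), r.start
        promoter = value_fn(r.chrom, plo, phi) if phi > plo else float("nan")
        rows.append(
            (
                r.gene_id,
                body / genome_mean if not np.isnan(body) else float("nan"),
                promoter / genome_mean if not np.isnan(promoter) else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "body_norm", "promoter_norm"])
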