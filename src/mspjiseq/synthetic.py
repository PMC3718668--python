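"""Synthetic genomes, methylomes, reads and WGBS-like counts with known truth.

The generator emulates the study design this package targets: a small plant
genome (~36% GC), context-dependent symmetric methylation, in silico MspJI
digestion, a 28-35 bp gel band, 50-bp single-end reads carrying the
sequencing adapter, and a per-site bisulfite-style count table.  Truth
alignments are emitted directly as SAM so no external aligner is needed.

All randomness flows from one integer seed through a single numpy Generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .digestion import (
    DigestResult,
    Fragment,
    MethylationState,
    SizeSelection,
    digest,
    joint_occurrences,
)
from .genome import Genome, GenomeSequence, revcomp
from .patterns import ASYMMETRIC, CnnrLocus, scan_cnnr_loci
from .qc import DEFAULT_ADAPTER, SequencedRead

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the whole synthetic pipeline."""

    seed: int
    genome_length: int = 100_000
    n_chromosomes: int = 1
    gc_content: float = 0.36  # Arabidopsis-like
    p_cg: float = 0.8
    p_chg: float = 0.3
    p_chh: float = 0.05
    coverage: int = 10
    read_length: int = 50
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.001
    size: SizeSelection = field(default_factory=SizeSelection)
    duplicate_block: Optional[tuple[int, int]] = None  # (block length, copies)
    template_seq: Optional[str] = None  # fixed single-chromosome genome

    def __post_init__(self) -> None:
        for name in ("gc_content", "p_cg", "p_chg", "p_chh", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def context_prob(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}[context]


#: The 40-bp single-CG toy genome: one YNCGNR site, one 32-bp fragment [3, 35).
TOY_SEQ = "A" * 16 + "TACGTA" + "A" * 18


def toy_config(seed: int = 0) -> SimConfig:
    return SimConfig(
        seed=seed,
        genome_length=len(TOY_SEQ),
        error_rate=0.0,
        p_cg=1.0,
        p_chg=1.0,
        p_chh=1.0,
        template_seq=TOY_SEQ,
    )


def toy_genome() -> Genome:
    return Genome([GenomeSequence("toy", TOY_SEQ)])


def genome_preset(seed: int = 1) -> SimConfig:
    """The default 100-kb round-trip preset."""
    return SimConfig(seed=seed)


PRESETS = {"toy": toy_config, "genome": genome_preset}


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """I.i.d. bases at the configured GC content, optional duplicated block."""
    if config.template_seq is not None:
        return Genome([GenomeSequence("chr1", config.template_seq)])
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per_chrom = config.genome_length // config.n_chromosomes
    chroms = []
    for i in range(config.n_chromosomes):
        idx = rng.choice(4, size=per_chrom, p=p)
        seq = "".join(BASES[j] for j in idx)
        if config.duplicate_block is not None and i == 0:
            blen, copies = config.duplicate_block
            if blen * (copies + 1) > per_chrom:
                raise ValueError("duplicate_block does not fit in the chromosome")
            block = seq[:blen]
            s = list(seq)
            gap = per_chrom // (copies + 1)
            for c in range(1, copies + 1):
                start = c * gap
                s[start : start + blen] = block
            seq = "".join(s)
        chroms.append(GenomeSequence(f"chr{i + 1}", seq))
    return Genome(chroms)


@dataclass(frozen=True)
class PlantedPair:
    """One planted symmetric site and its expected two-way fragment."""

    chrom: str
    plus_pos: int
    minus_pos: int
    category: str
    d: int
    frag_start: int
    frag_end: int

    @property
    def frag_length(self) -> int:
        return self.frag_end - self.frag_start


@dataclass
class TruthTable:
    """Ground truth of a simulated methylome.

    ``outcomes`` maps each planted pair to how digestion resolved it:
    "recovered" (its two-way fragment was released intact), "competing"
    (lost to competing cleavage with nearby methylated sites), "boundary"
    (cuts fall off the chromosome) or "off_band" (fragment released but
    outside the size-selection window).
    """

    pairs: list[PlantedPair] = field(default_factory=list)
    asymmetric_loci: list[CnnrLocus] = field(default_factory=list)
    outcomes: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def recovered_pairs(self) -> list[PlantedPair]:
        return [
            p
            for p in self.pairs
            if self.outcomes.get((p.chrom, p.plus_pos, p.minus_pos)) == "recovered"
        ]

    def competing_pairs(self) -> list[PlantedPair]:
        return [
            p
            for p in self.pairs
            if self.outcomes.get((p.chrom, p.plus_pos, p.minus_pos))
            in ("competing", "boundary")
        ]


def simulate_methylome(
    genome: Genome, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[MethylationState, TruthTable]:
    """Plant context-dependent methylation on the genome's CNNR loci.

    Symmetric sites (enumerated from plus-strand locus classification) are
    methylated jointly on both strands with their plus-strand context's
    probability; remaining loci are methylated independently with their own
    context's probability.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    loci = scan_cnnr_loci(genome)
    by_key = {l.key(): l for l in loci}
    methylated: set[tuple[str, int, str]] = set()
    truth = TruthTable()
    paired_keys: set[tuple[str, int, str]] = set()
    for locus in loci:
        if locus.strand != "+" or locus.category == ASYMMETRIC:
            continue
        minus_pos = locus.pos + locus.partner_offset_d
        partner_key = (locus.chrom, minus_pos, "-")
        if partner_key not in by_key:  # partner C unsequenced (N) etc.
            continue
        paired_keys.add(locus.key())
        paired_keys.add(partner_key)
        if rng.random() < config.context_prob(locus.context):
            methylated.add(locus.key())
            methylated.add(partner_key)
            d = locus.partner_offset_d
            truth.pairs.append(
                PlantedPair(
                    locus.chrom,
                    locus.pos,
                    minus_pos,
                    locus.category,
                    d,
                    minus_pos - 16,
                    locus.pos + 17,
                )
            )
    for locus in loci:
        if locus.key() in paired_keys:
            continue
        if rng.random() < config.context_prob(locus.context):
            methylated.add(locus.key())
            truth.asymmetric_loci.append(locus)
    state = MethylationState.from_keys(methylated)
    return state, truth


def record_digest_outcomes(
    truth: TruthTable, result: DigestResult, size: SizeSelection
) -> None:
    """Fill truth.outcomes by matching planted pairs against a digest."""
    emitted = {
        (f.chrom, f.start, f.end) for f in result.fragments if f.scenario in "EF"
    }
    destroyed = {(f.chrom, f.start, f.end) for f in result.destroyed}
    boundary = {l.key() for l in result.boundary_lost}
    for p in truth.pairs:
        key = (p.chrom, p.plus_pos, p.minus_pos)
        span = (p.chrom, p.frag_start, p.frag_end)
        if span in emitted:
            truth.outcomes[key] = (
                "recovered" if size.keeps(p.frag_length) else "off_band"
            )
        elif span in destroyed:
            truth.outcomes[key] = "competing"
        elif (p.chrom, p.plus_pos, "+") in boundary or (
            p.chrom,
            p.minus_pos,
            "-",
        ) in boundary:
            truth.outcomes[key] = "boundary"
        else:
            truth.outcomes[key] = "competing"


@dataclass(frozen=True)
class TruthAlignment:
    """One simulated read's true placement (insert coordinates)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str  # forward-strand insert sequence, errors included
    multiplicity: int


@dataclass
class SimReads:
    reads: list[SequencedRead]
    alignments: list[TruthAlignment]
    fragments: list[Fragment]
    digest: DigestResult
    n_errors: int = 0


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    err_pos = [i for i in range(len(seq)) if rng.random() < error_rate]
    if not err_pos:
        return seq, []
    s = list(seq)
    for i in err_pos:
        alt = [b for b in BASES if b != s[i]]
        s[i] = alt[int(rng.integers(0, 3))]
    return "".join(s), err_pos


def simulate_reads(
    genome: Genome,
    state: MethylationState,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    precomputed: Optional[DigestResult] = None,
) -> SimReads:
    """Digest, size-select and sequence: FASTQ-style reads plus truth SAM.

    Each size-selected fragment yields ``coverage`` reads from a uniformly
    random strand; the read is the insert plus adapter, padded with A to the
    read length, with substitution errors at ``error_rate`` (Q40 bases, Q10
    at errors).  Multiplicity is the genome-wide joint occurrence count of
    the insert and its reverse complement.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    result = precomputed if precomputed is not None else digest(genome, state)
    selected = [f for f in result.fragments if config.size.keeps(f.length)]
    reads: list[SequencedRead] = []
    alignments: list[TruthAlignment] = []
    n_errors = 0
    if not selected:
        warnings.warn("digestion produced no size-selected fragments")
    for fi, frag in enumerate(selected):
        chrom = genome[frag.chrom]
        insert = frag.sequence(chrom)
        mult = joint_occurrences(genome, insert)
        for ci in range(config.coverage):
            strand = "+" if rng.random() < 0.5 else "-"
            fwd_err, err_pos = _mutate(insert, rng, config.error_rate)
            n_errors += len(err_pos)
            oriented = fwd_err if strand == "+" else revcomp(fwd_err)
            read_seq = oriented + config.adapter
            if len(read_seq) < config.read_length:
                read_seq += "A" * (config.read_length - len(read_seq))
            read_seq = read_seq[: config.read_length]
            quals = [40] * len(read_seq)
            for i in err_pos:
                j = i if strand == "+" else len(insert) - 1 - i
                if j < len(quals):
                    quals[j] = 10
            rid = f"frag{fi:06d}c{ci:03d}|{frag.chrom}:{frag.start}-{frag.end}|{strand}"
            reads.append(SequencedRead(rid, read_seq, tuple(quals)))
            alignments.append(
                TruthAlignment(
                    rid, frag.chrom, frag.start, frag.end, strand, fwd_err, mult
                )
            )
    return SimReads(reads, alignments, selected, result, n_errors)


def write_truth_sam(
    alignments: list[TruthAlignment], genome: Genome, path: str | Path
) -> None:
    """Write truth alignments as a plain-text SAM with NH multiplicity tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": len(c)} for c in genome],
    }
    tid = {c.name: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = tid[aln.chrom]
            a.reference_start = aln.start
            a.mapping_quality = 60 if aln.multiplicity == 1 else 0
            a.cigarstring = f"{aln.end - aln.start}M"
            a.query_sequence = aln.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
            a.set_tag("NH", aln.multiplicity)
            out.write(a)


def simulate_wgbs(
    genome: Genome,
    state: MethylationState,
    coverage: float = 10.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cytosine methylated/total counts emulating a bisulfite experiment.

    total ~ Poisson(coverage); methylated ~ Binomial(total, 1 - error) at
    planted sites and Binomial(total, error) elsewhere.  Covers every
    cytosine on both strands.
    """
    rng = np.random.default_rng(seed)
    if state.mode == "all_cnnr":
        planted = {l.key() for l in scan_cnnr_loci(genome)}
    else:
        planted = set(state.methylated)
    rows = []
    for chrom in genome:
        seq = chrom.seq
        for pos, base in enumerate(seq):
            if base == "C":
                strand = "+"
            elif base == "G":
                strand = "-"
            else:
                continue
            rows.append((chrom.name, pos, strand, (chrom.name, pos, strand) in planted))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "planted"])
    total = rng.poisson(coverage, size=len(df))
    p = np.where(df["planted"], 1.0 - error_rate, error_rate)
    meth = rng.binomial(total, p)
    df["methylated_reads"] = meth
    df["total_reads"] = total
    return df[["chrom", "pos", "strand", "methylated_reads", "total_reads"]]


def simulate_gene_models(
    genome: Genome,
    n_genes: int,
    rng: np.random.Generator,
    gene_len: tuple[int, int] = (1000, 3000),
    spacing: int = 1500,
) -> pd.DataFrame:
    """Non-overlapping random gene models (chrom, start, end, strand, gene_id)."""
    rows = []
    gid = 0
    for chrom in genome:
        pos = spacing
        while pos + gene_len[1] + spacing < len(chrom) and gid < n_genes:
            length = int(rng.integers(gene_len[0], gene_len[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom.name, pos, pos + length, strand, f"gene{gid:04d}"))
            gid += 1
            pos += length + spacing + int(rng.integers(0, spacing))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(
                f"{r.chrom}\tmspjiseq\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.gene_id}\n"
            )


def simulate_all(config: SimConfig) -> tuple[Genome, MethylationState, TruthTable, SimReads]:
    """Run the full generator chain under one seed."""
    genome = simulate_genome(config)
    state, truth = simulate_methylome(genome, config)
    sim = simulate_reads(genome, state, config)
    record_digest_outcomes(truth, sim.digest, config.size)
    return genome, state, truth, sim
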