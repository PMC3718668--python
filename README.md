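# mspjiseq

Toolkit for **MspJI-seq**: detecting 5-methylcytosine by digesting genomic
DNA with the modification-dependent restriction endonuclease MspJI,
sequencing the size-selected fragments, and mapping the reads back to
recognition-site geometry.  It is aimed at people building or evaluating
enzyme-enrichment methylation assays — method developers who need an
in-silico digestion model with known ground truth, and analysts who need to
call methylated sites from MspJI libraries and compare them with bisulfite
data.

## The model

MspJI recognizes `mC N N R` (R = A or G) and cuts both strands at N12/N16
on the 3' side of the methylcytosine, leaving a 4-base 5' overhang.  After
end repair, the insert released between a minus-strand mC at `q` and a
plus-strand mC at `p` spans `[q-16, p+17)` in 0-based half-open
coordinates, so its length obeys

```
L = 33 - d,        d = q - p
```

Symmetric sites — both strands methylatable, `d` in {-2..5} \ {0} — release
28-35 bp two-way fragments, which is exactly the gel band the protocol
retains.  The seven symmetric categories are YNCGNR (32 bp), YCHGR (31),
CHHG (30), CYHAG (29), CHYAHG (28), TDDGCHHA (34) and TDDGNCHHA (35).
Cleavage around neighbouring sites follows six scenarios (independent,
competing, one-way, two-way) depending on strands and spacing; the engine
resolves them deterministically and records competing-cleavage losses.
Calling inverts the geometry: a mapped insert `[start, end)` supports a
plus-strand mC at `end-17` and a minus-strand mC at `start+16` whenever the
reference carries a CNNR there.  Per-site depth is the absolute methylation
level; per-region read density and the mC/CNNR fraction are the two
relative methylation levels.  See `docs/methods.md` for the full model.

## Worked example

Simulate a 100-kb genome with a CG-dominated methylome, digest, sequence,
QC and call, all from the command line:

```
$ mspji simulate --preset genome --seed 1 -o sim
simulate: 1 chromosome(s), 967 planted pairs, 490 selected fragments, 4900 reads

$ mspji census sim/genome.fa -o census.tsv
census: 4675 symmetric sites, generation rate 26.08%, CNNR fraction 50.3%

$ mspji qc sim/reads.fastq -o clean.fastq --drop-log dropped.tsv
qc: 4900 in, 4900 kept (4900 trimmed), 0 dropped

$ mspji call sim/truth.sam sim/genome.fa --unique-only -o calls.tsv
call: 4900 fragments -> 751 site calls (mapping rate 100.00%)

$ head -8 calls.tsv
# clean_reads   4900
# mapping_rate  1.0000
# unique_rate   1.0000
# spectrum      28:440,29:330,30:560,31:740,32:2000,33:240,34:280,35:310
chrom   pos     strand  context category        depth
chr1    73      +       CG      YNCGNR  10
chr1    74      -       CG      YNCGNR  10
chr1    310     +       CG      YNCGNR  10
```

Reading the output: 967 symmetric sites were planted as methylated pairs;
digestion plus the 28-35 bp size selection released 490 fragments (the rest
are lost to competing cleavage between nearby methylated sites, as the
model predicts for dense methylation).  Every fragment was sequenced to
depth 10 with adapters, all reads survive QC, and the caller recovers
methylated cytosines as strand-paired CG loci (e.g. positions 73/74) each
supported by exactly the simulated coverage.  The insert-length spectrum
peaks at 32 bp — the symmetric CpG category.  On the census side, 26.08% of
this synthetic genome's cytosines sit in size-selectable symmetric sites,
and 50.3% of cytosines are in CNNR context (for an i.i.d. genome the
expected fraction is exactly one half).

The same operations are available as a library (`mspjiseq.digestion`,
`mspjiseq.caller`, `mspjiseq.assessment`, `mspjiseq.synthetic`), including
metagene profiling, multi-mapper resampling, replicate correlation and
binomial WGBS-style calling.

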