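# Methods

## The enzymatic model

MspJI is a modification-dependent restriction endonuclease.  It recognizes a
5-methylcytosine in the context `mC N N R` (R = A or G) and introduces a
double-strand break at a fixed distance on the 3' side of the methylcytosine:
after the 12th nucleotide on the mC strand and after the 16th on the opposite
strand, leaving a four-base 5' overhang.  In the package's 0-based half-open
coordinates, a plus-strand mC at position `p` yields cut coordinates `p+13`
(near, mC strand) and `p+17` (far, opposite strand); a minus-strand mC at `q`
mirrors leftward to `q-12` and `q-16`.

Library end-repair fills in the 5' overhangs, so the double-stranded insert
that is actually sequenced runs from outer cut to outer cut.  The released
product between two neighbouring breaks is `[left_break_min, right_break_max)`
— each break donates its 4-base overhang to *both* flanking products.  For a
symmetric site (plus mC at `p`, minus mC at `q`, offset `d = q - p`) the
two-way fragment spans `[q-16, p+17)`, giving the length law

    L = 33 - d.

The seven symmetric site categories and their fragment lengths follow
directly: YNCGNR (d=+1, 32 bp), YCHGR (+2, 31), CHHG (+3, 30), CYHAG (+4,
29), CHYAHG (+5, 28), TDDGCHHA (-1, 34), TDDGNCHHA (-2, 35).  Size-selecting
28-35 bp fragments therefore retains exactly the two-way symmetric band.

Note that only YNCGNR, TDDGCHHA and TDDGNCHHA are palindromic as IUPAC
classes; the other four are not their own reverse complements (H complements
to D).  "Symmetric" here means the site carries a methylatable CNNR on both
strands — a property every concrete instantiation of all seven patterns has,
which the test suite verifies by exhaustive expansion.  The census counts
forward-strand pattern matches only; a handful of genuine double-strand sites
whose forward-strand spelling is the reverse-complement pattern (e.g. CDDG
for CHHG) are deliberately not tabulated, which keeps the census convention
consistent with the published per-category totals and makes the overall
recovery estimate conservative.

## The cleavage-scenario engine

Cleavage around two neighbouring methylated sites falls into six scenarios,
classified from the strands and the distance between the methylcytosines:

* **A** — same strand, >= 12 bp apart: independent cuts; the one-way product
  between the breaks carries one recognition site.
* **B** — same strand, < 12 bp: competing cleavage; only a cut terminus.
* **C** — opposite strands cutting toward each other, d >= 29: a released
  middle product with no recognition site.
* **D** — toward each other, 16 <= d <= 28: competing cleavage, terminus only.
* **E** — toward each other, 1 <= d <= 15: two-way cleavage, an 18-32 bp
  fragment containing both sites.
* **F** — opposite strands cutting away from each other: two-way, >= 34 bp.

The engine sorts methylated loci per chromosome by outer-cut coordinate
(ties by position), classifies each adjacent pair, and emits the
between-break product for A/C/E/F pairs and a terminus record for B/D
pairs.  A candidate product survives only if no *other* methylated site's
4-base break window intersects its open interior; products lost this way are
recorded as competing-cleavage casualties.  This interior-break rule is what
makes the left-to-right pair resolution equal, fragment for fragment, an
independent brute-force oracle that enumerates all plus/minus locus pairs and
intersects their cut intervals — an equivalence the acceptance suite checks
on 200 random 2-kb genomes under the all-methylated assumption.  Chains of
many nearby methylated sites are thereby handled deterministically: whatever
two-way fragments remain are exactly those whose interiors no competing break
reaches.  Cuts falling off a chromosome end remove the locus from digestion
(recorded separately); no fragment ever crosses a chromosome boundary.

Competing cleavage (B/D) deliberately produces no fragment: the real
products of competing cleavage depend on cutting order and are not
predictable, so fabricating them would plant artefacts downstream.  The
engine is wobble-free; the enzyme's known one-base cut wobble is handled at
calling time only.

## Census conventions

The census counts forward-strand matches of the seven category patterns
(overlapping matches all counted, each match = one symmetric locus = two
methylatable cytosines), the genome's total cytosines as forward C plus G
(i.e. both strands), and the generation rate as cytosines-in-sites over
total cytosines.  A cytosine lying in two overlapping category windows is
counted once per window; the 2x consistency (cytosines-in-sites equals twice
the summed locus counts) holds by construction and is asserted in tests.
Genome letter N matches no pattern code, including pattern N: sites are never
called on unsequenced bases.  Lowercase (soft-masked) bases are uppercased at
load and masking is ignored.

When a locus window satisfies several category patterns, classification
precedence is longest-pattern-first (TDDGNCHHA > TDDGCHHA > CHYAHG > CYHAG >
YNCGNR/YCHGR/CHHG), first match wins.  The shorter patterns are mutually
exclusive by construction (their context positions differ), so precedence
only matters against the two long TDDG patterns.

## Read QC and trimming

Reads are dropped when more than 30% of bases are N or more than 10% of
bases fall below Phred 20 — both strict inequalities, read fractions, with
Phred+33 encoding assumed.  Adapter trimming removes the longest suffix of
the read equal to a prefix of the configured adapter (default: Illumina
TruSeq read-1, `AGATCGGAAGAGC...`), minimum overlap 5 bases, exact match
only, single pass.  Trimming is idempotent except in the ~4^-5 coincidence
that the recovered insert itself ends in an adapter prefix; a fixpoint loop
would instead over-trim real inserts, which matters more for a library whose
whole signal is a 28-35 bp insert length.

## Site calling

The caller inverts the two-way geometry: for a mapped insert `[start, end)`
the candidate methylcytosines sit at `end-17` (plus strand) and `start+16`
(minus strand).  A candidate is accepted iff the *reference* carries a CNNR
at that position/strand — read bases are never consulted, so substitution
errors cannot create false sites, only (rarely) break the alignment itself.
With `wobble=1` the positions one base either side are retested when the
exact offset fails, which recovers the off-centre CpG seen in 33-bp
fragments.  Depth is counted per fragment (a two-way fragment supports both
of its loci) and duplicates are not collapsed: fragment count is the
methylation signal and the 6-cycle single-end library makes PCR duplicates
unresolvable.  One-way products whose methylcytosine lies outside the insert
are not callable at these offsets — an accepted sensitivity loss consistent
with the method's two-way design.

Multiplicity comes from the NH tag or from counting alignment records per
read name (both SAM dialects).  Multi-mapper region annotation resamples one
position per read uniformly, 1000 draws by default, and averages per-region
counts; summed means equal the read count exactly (mass conservation).

Region-level "relative methylation" has two deliberate variants, reflecting
the two printed definitions: read density (fragments whose notarized locus
falls in the interval) and the mC/CNNR fraction (called loci over CNNR loci
in the interval).  Both are emitted and named distinctly.

## Assessment

WGBS-style calls use a one-sided binomial test of methylated reads against
the bisulfite error rate with Benjamini-Hochberg control (defaults: error
0.01, FDR 0.05 — these parameters are not fixed by the enrichment method
itself and are exposed as configuration), or the looser
any-supporting-read rule (`mode=any_read`).  Specificity/sensitivity
comparisons restrict both call sets to peak regions and to symmetric CGNR
loci whose 32-bp inserts (plus reverse complement) occur exactly once
genome-wide.  Repeatability is the Pearson correlation of per-peak site
counts or summed depths; peaks are consumed as BED, and common peaks across
replicates are >= 1 bp intersections, merged.

Metagene profiles divide each stranded region into 20 equal bins plus 1 kb
flanks in 100-bp bins (minus-strand regions reversed so bin 1 is the TSS
side), averaging a value function across regions with NaN for empty or
clipped bins; regions shorter than 20 bp are skipped.  Per-gene
normalization divides gene-body and promoter (default 1 kb upstream,
strand-aware) methylation by the genome-wide length-weighted mean — the
normalization scheme is this package's choice and is labelled in output.

## The synthetic generator

`mspjiseq.synthetic` emulates the study design end to end: an i.i.d. genome
at 36% GC (one or more chromosomes, optional duplicated blocks as repeat
mimics, optional random gene models), context-dependent methylation
(defaults p_CG = 0.8, p_CHG = 0.3, p_CHH = 0.05 — a methylome dominated by
symmetric CpG methylation with realistic minority non-CpG classes),
digestion + 28-35 bp size selection, 50-bp single-end reads at coverage 10
built as insert + adapter with substitution errors at rate 0.001 (Q40
bases, Q10 at errors), truth alignments written directly as SAM so no
external aligner is needed, and Poisson/binomial per-cytosine bisulfite
counts.  Symmetric sites are methylated jointly on both strands with the
plus-strand context's probability; remaining loci independently.  The truth
table records, for every planted pair, whether digestion recovered its
fragment or lost it to competing cleavage or a chromosome boundary, so
sensitivity accounting can separate caller misses from losses that are
unrecoverable by design.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: dinucleotide composition biases such as
CpG depletion, genome-scale repeat structure (beyond explicit duplicated
blocks), indel or quality-profile errors, PCR duplication, partial
digestion, and aligner behaviour (truth alignments are exact).  Real-data
mapping rates, peak counts and replicate correlations depend on exactly
these features and are out of reach of desk-scale synthesis.

All randomness flows from one integer seed through numpy Generators;
identical seeds give byte-identical outputs.

## Problem sizes in `scripts/acceptance.py`

The acceptance script recomputes every headline quantity from scratch under
one seed: census and CNNR fraction on a 1-Mb synthetic genome; the length
law over all seven constructed category sites; engine-vs-oracle equivalence
on 50 random 2-kb genomes; exact-match mappability with 200 draws per
length (28-35) on a 200-kb genome; the full simulate → QC → call round trip
on the 100-kb preset; the binomial caller's null behaviour on 10,000
unmethylated sites at coverage 10; and two-replicate repeatability on a
40-kb genome with 2-kb peaks.  These sizes keep the whole script under a
minute on one CPU while leaving every statistic's sampling error far inside
the asserted margins.

## Known limitations

* The whole-genome census convention (forward-strand pattern matches only)
  reproduces the published per-category accounting but undercounts
  double-strand sites whose forward spelling is a non-palindromic pattern's
  reverse complement.
* Scenario A one-way products have no defined "sequenced end"; the engine
  emits the full between-cut product and lets size selection decide, so a
  small number of one-way products enter the band and can contribute calls
  at their geometric offsets.
* The exact per-read recognition offsets of the original pipeline are not
  published; the offsets here are derived from the cut model and validated
  by the round-trip property (digest → notarize returns exactly the planted
  loci), not against the original code.
* Competing-cleavage products are modelled as pure losses; if the enzyme in
  fact releases partial products at usable lengths, real sensitivity would
  differ from the simulated one.
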