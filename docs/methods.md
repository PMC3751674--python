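# Methods

This note documents the models, conventions and numerical choices behind
`lncmir`, in the order the pipeline runs.

## Annotation and the lncRNA set

Coordinates are 0-based half-open internally; GTF is read and written
1-based inclusive, BED output 0-based. Spliced sequences are extracted
strand-aware (minus-strand transcripts reverse-complemented), so all
scanning happens in sense-strand DNA space.

The lncRNA set keeps genes whose transcript biotypes are all in
{antisense, lincRNA, non_coding, processed_transcript}. Exclusions are
applied in a fixed precedence (pseudogene → non-lnc biotype → short isoform
→ coding symbol) and exactly one reason is recorded per excluded gene.
Pseudogene detection is substring-based (any biotype containing
"pseudogene"), symbol matching is case-insensitive exact match — symbol
lists mix cases across sources.

"Intergenic" is measured between gene spans (outermost transcript bounds),
ignoring strand: the gap must be ≥ 10 kb (configurable) to every other
annotated gene on the chromosome. Overlapping genes are never intergenic,
at any threshold; abutting genes have gap 0. Gene-span distance is the most
conservative reading of genomic separation.

## Site types and scanning

A seed is microRNA positions 2–8 over ACGU; patterns are converted to DNA
once and matched exactly (no wobble pairs, no 6mers, no context scores —
out of scope by design). Site types: 8mer = reverse complement of the seed
plus a downstream A (8 nt), 7mer-m8 = reverse complement alone (7 nt),
7mer-A1 = reverse complement of seed positions 2–7 plus the A. The
position-1 A is part of the match string, so it participates in
conservation as part of the site.

Each transcript position keeps only its best site type
(8mer > 7mer-m8 > 7mer-A1): an 8mer suppresses the 7mer-m8 it starts with
and the 7mer-A1 it contains at the next position. This keeps strata
disjoint so counts add. Overlapping matches at different positions are all
reported. The scanner is verified against a brute-force
position-by-position oracle.

Sites are mapped to genome coordinates through the exon structure;
junction-spanning sites record one genomic interval per exon segment and
the position of their transcript-5′-most base. Counting is per transcript,
then deduplicated to gene level by (gene, genomic position, family, site
type) so isoform-shared sites count once per gene.

## Conservation tiers

Species are grouped into three exclusive sets — primates, non-primate
placental mammals, non-mammal vertebrates — and tiers are *nested*:
the mammal tier includes the primates, the vertebrate tier includes
everything. Nesting makes stratum counts monotone in stringency.

A species is *intact* over a site iff its aligned sequence across the
site's reference columns equals the site's match string exactly: no
substitutions, no gaps in the species row, and no insertion columns inside
the site (a reference-row gap breaks the site for every species). This
exact-identity rule is the strictest defensible reading of per-species
presence.

The tier is the deepest nested clade whose intact fraction reaches
`min_fraction` (default 0.5), requiring every shallower clade to pass too.
Fractions are computed over aligned **non-reference** species: the
reference genome trivially contains its own site, so counting it would let
a site intact nowhere else pass a 2-primate clade at the 0.5 threshold.
The reference itself is a hard gate (`require_reference`, default on): if
its row disagrees with the site the tier is `none`. Species absent from a
block are excluded from the denominator (absence of alignment is not
evidence of loss); `absent_counts_against` flips that. A clade with no
non-reference species aligned passes vacuously — with the default
threshold this only matters for degenerate alignments.

A fractional threshold was chosen over an all-species requirement because
alignment dropout in deep multi-species MAFs makes all-species intactness
unrealistically strict; the threshold is configuration and is recorded in
run metadata.

## The dinucleotide null

"Dinucleotide-preserving" is implemented as a generative first-order
Markov chain over ACGU fitted to the pooled real seeds: initial
distribution from position-1 nucleotides, transition matrix from all
adjacent pairs, both with add-one smoothing (87 × 6 observed transitions
can miss rare dinucleotides, and a zero row would make sampling
undefined). A fitted generative model, rather than per-seed shuffling, is
the only way to draw 20 diverse sets of ~87 seeds — 7-mers admit very few
distinct dinucleotide-preserving shuffles.

Random draws identical to a real seed are rejected and redrawn (a true
seed inside the null would absorb real signal); duplicates within a set
are allowed, since distinct families can share composition. Random sets
run through *exactly* the same counting function as the real seeds —
pipeline identity is asserted in the tests by feeding the real set through
the null path and requiring equality.

## Enrichment statistics

Expected = arithmetic mean of the per-set counts; ratio =
observed/expected. The mean of per-set ratios is also computed and kept as
metadata (`ratio_mean_of_ratios`): ratio-to-mean is the primary statistic
because it stays stable when individual per-set counts are small.
Empirical *P* = #{sets with count ≥ observed}/n, ties counting against the
observed (conservative). With the standard 20 sets the quantized labels
are: *P* ≤ 0.05 at ≥ 19/20 sets below observed, *P* = 0.10 at exactly
18/20; with any other set count the labels are suppressed and the raw
fraction is reported. FDR = expected/observed capped at 1 — the estimated
fraction of reported sites attributable to chance, the reciprocal of the
ratio (1.8× ⇔ 56%). No multiple-testing correction is applied across the
stringency grid; strata are descriptive. Strata with expected < 1 count
are flagged unreliable ("n/a") rather than given a ratio.

## Localization

Libraries are scaled to counts per million; cytoplasmic and nuclear CPM
are pooled across cell lines before the ratio (robust to zeros in
individual lines; a per-cell-line-median alternative is provided). A
pseudocount of 0.5 CPM on each side avoids division by zero. The depth
filter (≥ 20 raw reads across all libraries) runs on raw counts, as it
models mapped-read evidence, and is what protects against the huge ratios
a handful of reads can produce. Classification is gene-level.

## Synthetic data generator

The generator emulates the five study inputs with known ground truth. Its
deliberate simplifications, and what they imply for test conclusions:

* **Background sequence** is i.i.d. with configurable GC (default 0.41,
  human-like). Real transcripts have higher-order composition; the i.i.d.
  background still exercises the dinucleotide null non-trivially through
  seed composition, but passing tests do not certify behaviour on, e.g.,
  CpG-depleted or repeat-rich sequence.
* **Species tree** is a star within each clade group (independent
  substitutions from the reference at per-clade rates, default
  0.05/0.15/0.45 per site, monotone with depth). Conservation calls are
  presence/absence per species, not phylogeny-aware, so a star suffices;
  correlated substitution along a real tree is not modelled.
* **Gene models** are single-exon, laid out on one chromosome with fixed
  spacing (default 12 kb, so the default set is intergenic); coding
  transcripts carry UTR5/CDS/UTR3 (defaults 150/600/800 nt), lncRNAs are
  1 kb. Junction-spanning sites are exercised by hand-built fixtures, not
  by the generator.
* **Species counts** default to 3 primates / 4 mammals / 8 non-mammal
  vertebrates. The vertebrate group deliberately outnumbers
  primates + mammals so a mammal-conserved site cannot pass the nested
  vertebrate threshold by arithmetic alone.
* **Counts** are negative binomial with dispersion 0.1 (a standard
  over-dispersed RNA-seq model); cytoplasmic genes get 4:1 expected
  cytoplasm:nucleus per library, others 1:4, across 7 simulated cell
  lines; a configurable fraction of genes (default 10%) is simulated at
  near-zero depth to exercise the 20-read filter.

**Planted enrichment.** For target factor *e*, each conserved family
receives round((e−1)·E) extra 8mer sites, where E is the *analytic*
expected count of background sites reaching the planted tier:
(number of 8mer positions) × (i.i.d. match probability of the family's
8mer) × (exact clade-pass probability from binomial enumeration, matching
the caller's non-reference-fraction rule). Planted sites are written
verbatim into host transcripts at non-overlapping positions, held
invariant in every species of the planted tier's clades, and forced to ≥ 2
mismatches in deeper clades. Background sites accrue identically to
observed and expected counts, so the expected recovered ratio equals *e*;
with *e* = 1 nothing is planted and the dataset is an exact null. Requests
exceeding the non-overlapping window capacity fail up front.

All outputs are a deterministic function of one RNG seed — identical
configurations produce byte-identical files.

## Problem sizes used in validation

Parameter recovery runs 10 replicate datasets of 2,000 lncRNA transcripts
(1 kb each) with 20 conserved families planted at 1.8× in the mammal tier
(the acceptance script; the test suite uses 1,000 transcripts of 800 nt
for the same check). Null calibration runs 50 replicates of 300
transcripts with nothing planted, requiring the mean mammal-8mer ratio in
[0.9, 1.1] and ≤ 10% of strata at the quantized *P* ≤ 0.05 flag. Scanner
correctness is checked against the brute-force oracle on 1,000 random
sequences. Small self-consistency fixtures use stronger planted factors
(6–8×) because at fixture scale a 1.8× request rounds the per-family
planted count to zero.

## Known limitations

* Conservation is presence/absence per species; branch-length-aware scores
  (PhyloP/PhastCons-style) and indel-aware realignment are out of scope.
* Sites spanning two MAF blocks are treated as unalignable (tier `none`);
  the generator emits one block per transcript so this only affects
  fragmented external alignments.
* The enrichment grid reports each stratum independently; cross-stratum
  dependence (nested tiers share sites by construction) is intentional and
  must be kept in mind when reading the tables.
* The localization normalization ("CPM pooled across lines") is one
  defensible reading of normalized cytoplasm/nucleus ratios; the
  per-line-median variant is provided for sensitivity analysis.
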