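# lncmir

Detection of evolutionarily conserved microRNA target sites in long
non-coding RNAs (lncRNAs), as a tested, reusable Python pipeline.

Comparative genomics shows that most protein-coding 3′UTRs carry microRNA
seed matches at frequencies far above chance, a signature of conserved
microRNA control. Whether lncRNAs — long (>200 nt) transcripts without
coding capacity, often only patch-wise conserved — carry the same signature
is much less clear. `lncmir` implements the complete analysis needed to ask
that question on any annotation/alignment bundle, and ships a synthetic-data
generator with planted signal so every stage is testable without external
downloads.

## What the pipeline computes

1. **lncRNA set construction** — from a GENCODE-dialect GTF: keep genes whose
   every isoform has a long-non-coding biotype (`antisense`, `lincRNA`,
   `non_coding`, `processed_transcript`), drop pseudogenes, genes with any
   isoform < 200 nt, and genes whose symbol matches a user-supplied coding
   list; optionally restrict to *intergenic* lncRNAs ≥ 10 kb from any other
   gene.
2. **Seed-site scanning** — each microRNA family seed (positions 2–8)
   expands into the canonical site types 8mer, 7mer-m8 and 7mer-A1; spliced
   transcript sequences are scanned for exact matches, each locus keeping its
   best site type, and hits are mapped back to genome coordinates through the
   exon structure.
3. **Conservation tiers** — from a reference-anchored MAF: a site is intact
   in a species when it aligns gaplessly and identically; the site's tier is
   the deepest nested clade (primate ⊂ placental mammal ⊂ vertebrate) in
   which ≥ 50% of aligned non-reference species are intact.
4. **Dinucleotide null** — a first-order Markov model fitted to the real
   seeds generates 20 sets of composition-matched random seeds (each set as
   large as the real conserved-family set, the field-standard design),
   which run through the *identical* scan + conservation path.
5. **Enrichment statistics** — per stringency stratum (tier × site type ×
   transcript subset × family class):
   ratio = observed / mean(random-set counts); empirical
   *P* = #{sets ≥ observed}/20, so ≥ 19/20 sets below observed gives
   *P* ≤ 0.05 and 18/20 gives *P* = 0.10; FDR = expected/observed
   (a 1.8× enrichment ⇔ 56% FDR).
6. **Subcellular localization** — from nuclear/cytoplasmic fraction count
   matrices: per-library CPM, pooled across cell lines; cytoplasmic ⇔
   ratio > 1 and ≥ 20 raw reads over all libraries.

## Worked example

```bash
cd examples
python 01_simulate_dataset.py   # writes ./example_data with known ground truth
python 04_null_and_enrichment.py
```

The generator plants 8mer sites for each conserved family at a configurable
multiple of the dinucleotide expectation (here 6×), intact through the
placental-mammal clade and broken beyond it. The enrichment step then prints:

```
observed mammal-tier 8mer sites : 28
expected (mean of 20 null sets) : 5.75
enrichment ratio                : 4.87
empirical P                     : 0.00 (P<=0.05)
implied FDR                     : 0.21
```

28 mammal-tier 8mer sites were observed against ~5.8 expected from 20
composition-matched random seed sets: the planted signal is recovered as a
strong, significant enrichment (the recovered ratio sits below the planted
6× because background sites accrue to both observed and expected counts).
The remaining examples cover scanning, conservation tiers, localization and
the full `run_pipeline` bundle; `lncmir --help` exposes the same stages as a
CLI (`simulate`, `annotate`, `scan`, `conserve`, `null`, `localize`,
`enrich`, `run`).

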