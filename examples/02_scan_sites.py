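"""Expand a microRNA seed into its site patterns and scan a transcript.

Uses the let-7 seed (GAGGUAG). The three site types in decreasing
stringency: 8mer (seed match + downstream A), 7mer-m8 (seed match alone),
7mer-A1 (6-nt core + A).
"""

from lncmir import SeedFamily, scan_transcript, seed_to_patterns
from lncmir.models import TranscriptModel

let7 = SeedFamily("let-7", "GAGGUAG", "conserved")
for p in seed_to_patterns(let7):
    print(f"{p.site_type:8s} -> {p.match_dna}")

transcript = TranscriptModel(
    transcript_id="T1",
    gene_id="G1",
    chrom="chr1",
    strand="+",
    exons=[(1000, 1030)],
    spliced_seq="AACTACCTCAGGGGGGCTACCTCGGGGGGG",
)
sites = scan_transcript(transcript, seed_to_patterns(let7))
print()
for s in sites:
    print(
        f"{s.site_type:8s} at transcript pos {s.transcript_pos:2d} "
        f"(genome {s.genome_chrom}:{s.genome_pos}) match {s.match_dna}"
    )
print(
    "\nThe first locus carries the full 8mer (its contained 7mers are\n"
    "suppressed: each position keeps only its best site type); the second\n"
    "locus lacks the downstream A and stays a 7mer-m8."
)
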