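"""Generate a small synthetic dataset with planted conserved target sites.

Writes the five pipeline inputs (genome FASTA, multi-species MAF, GTF,
seed-family table, fraction count matrix) to ./example_data and prints the
ground truth: how many 8mer sites were planted at the mammal conservation
tier and which genes were simulated as cytoplasmic.
"""

from lncmir import SimConfig, generate_dataset

config = SimConfig(
    seed_rng=7,
    n_coding_genes=5,
    n_lncrna_genes=80,
    lnc_len=800,
    n_seed_families_conserved=10,
    n_seed_families_nonconserved=3,
    planted_enrichment=6.0,
    planted_site_tier="mammal",
)
truth = generate_dataset(config, "example_data")

print(f"planted 8mer sites           : {len(truth.planted_sites)}")
print(f"simulated cytoplasmic genes  : {len(truth.true_cytoplasmic_genes)}")
for ps in truth.planted_sites[:5]:
    print(f"  {ps.gene_id} pos {ps.transcript_pos:4d} {ps.family_name} ({ps.tier})")
print(
    "\nEach planted site is an exact 8mer written into a lncRNA transcript,\n"
    "held intact in every primate and placental-mammal species of the\n"
    "alignment and broken in the non-mammal vertebrates, so the pipeline\n"
    "should recover it in the mammal conservation tier."
)
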