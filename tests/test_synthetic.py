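"""Synthetic dataset generator: determinism, planted sites, count model."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from Bio import AlignIO
from pyfaidx import Fasta

from lncmir.localization import FractionCounts, classify_localization
from lncmir.models import reverse_complement
from lncmir.synthetic import (
    GroundTruth,
    SimConfig,
    generate_counts,
    generate_dataset,
    spontaneous_tier_prob,
)

SMALL = dict(
    n_coding_genes=3,
    n_lncrna_genes=40,
    lnc_len=600,
    n_seed_families_conserved=8,
    n_seed_families_nonconserved=2,
    intergenic_spacing=11_000,
)


def file_hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
    }


@pytest.fixture(scope="module")
def planted_dataset(tmp_path_factory):
    # a strong planted factor keeps this small self-consistency fixture from
    # rounding the per-family planted count down to zero
    cfg = SimConfig(seed_rng=11, planted_enrichment=8.0, planted_site_tier="mammal",
                    clade_divergence={"primate": 0.05, "mammal": 0.15, "vertebrate": 0.3},
                    **SMALL)
    out = tmp_path_factory.mktemp("planted")
    truth = generate_dataset(cfg, out)
    return cfg, out, truth


class TestDeterminism:
    def test_identical_config_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed_rng=5, planted_enrichment=1.5, **SMALL)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, a)
        generate_dataset(SimConfig(seed_rng=5, planted_enrichment=1.5, **SMALL), b)
        assert file_hashes(a) == file_hashes(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(SimConfig(seed_rng=5, **SMALL), a)
        generate_dataset(SimConfig(seed_rng=6, **SMALL), b)
        assert file_hashes(a)["genome.fa"] != file_hashes(b)["genome.fa"]


class TestPlantedSites:
    def test_ground_truth_sites_verbatim_in_genome(self, planted_dataset):
        cfg, out, truth = planted_dataset
        assert len(truth.planted_sites) >= 1
        genome = Fasta(str(out / "genome.fa"), as_raw=True, sequence_always_upper=True)
        for ps in truth.planted_sites:
            g = genome[ps.chrom][ps.genome_start : ps.genome_start + 8]
            expect = ps.pattern if ps.strand == "+" else reverse_complement(ps.pattern)
            assert g == expect

    def test_maf_intact_in_tier_broken_in_deeper_clades(self, planted_dataset):
        cfg, out, truth = planted_dataset
        sites_by_chrom = [(ps.genome_start, ps) for ps in truth.planted_sites]
        checked = 0
        with open(out / "alignment.maf") as fh:
            for block in AlignIO.parse(fh, "maf"):
                rows = {rec.id.split(".")[0]: str(rec.seq).upper() for rec in block}
                ref_row = rows[cfg.reference_species]
                start = next(
                    rec.annotations["start"]
                    for rec in block
                    if rec.id.split(".")[0] == cfg.reference_species
                )
                for gpos, ps in sites_by_chrom:
                    off = gpos - start
                    if not 0 <= off <= len(ref_row) - 8:
                        continue
                    window = slice(off, off + 8)
                    for sp, row in rows.items():
                        clade = (
                            "primate" if sp.startswith("prim")
                            else "mammal" if sp.startswith("mamm")
                            else "vertebrate"
                        )
                        mism = sum(
                            a != b for a, b in zip(row[window], ref_row[window])
                        )
                        if clade in ("primate", "mammal"):  # planted tier: mammal
                            assert mism == 0, (sp, ps)
                        else:
                            assert mism >= 2, (sp, ps)
                    checked += 1
        assert checked >= len(truth.planted_sites)

    def test_reference_maf_rows_match_fasta(self, planted_dataset):
        # validated internally by load_maf when given the FASTA
        from lncmir.conservation import load_maf, read_clade_table

        cfg, out, truth = planted_dataset
        clades = read_clade_table(out / "clades.tsv")
        index = load_maf(out / "alignment.maf", clades, fasta=out / "genome.fa")
        assert index.query("chr1", 11_000, 11_008) is not None

    def test_null_config_plants_nothing(self, tmp_path):
        cfg = SimConfig(seed_rng=2, planted_enrichment=1.0, **SMALL)
        truth = generate_dataset(cfg, tmp_path / "null")
        assert truth.planted_sites == []

    def test_too_short_transcript_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="too short"):
            generate_dataset(
                SimConfig(seed_rng=1, lnc_len=6, n_lncrna_genes=2, n_coding_genes=1),
                tmp_path / "x",
            )

    def test_impossible_enrichment_rejected(self, tmp_path):
        cfg = SimConfig(
            seed_rng=1,
            n_coding_genes=1,
            n_lncrna_genes=5,
            lnc_len=9,  # at most one plantable window per transcript
            planted_enrichment=1e7,
            n_seed_families_conserved=1,
            n_seed_families_nonconserved=1,
            intergenic_spacing=30,
        )
        with pytest.raises(ValueError, match="[Ii]mpossible|capacity"):
            generate_dataset(cfg, tmp_path / "x")


class TestSpontaneousTierProb:
    def test_monotone_in_divergence_and_tier(self):
        lo = SimConfig(clade_divergence={"primate": 0.01, "mammal": 0.05, "vertebrate": 0.2})
        hi = SimConfig(clade_divergence={"primate": 0.1, "mammal": 0.3, "vertebrate": 0.5})
        for tier in ("primate", "mammal", "vertebrate"):
            assert spontaneous_tier_prob(lo, tier) > spontaneous_tier_prob(hi, tier)
        cfg = SimConfig()
        assert (
            spontaneous_tier_prob(cfg, "primate")
            >= spontaneous_tier_prob(cfg, "mammal")
            >= spontaneous_tier_prob(cfg, "vertebrate")
        )

    def test_zero_divergence_is_certain(self):
        cfg = SimConfig(clade_divergence={"primate": 0.0, "mammal": 0.0, "vertebrate": 0.0})
        for tier in ("primate", "mammal", "vertebrate"):
            assert spontaneous_tier_prob(cfg, tier) == pytest.approx(1.0)


class TestGenerateCounts:
    def test_cytoplasmic_gene_recovers_in_monte_carlo(self):
        cfg = SimConfig(mean_depth=100.0, low_expression_fraction=0.0)
        truth = GroundTruth(true_cytoplasmic_genes={"G1"})
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(200):
            df = generate_counts(["G1"], truth, cfg, rng)
            cyt = df.filter(like="_cytoplasm").to_numpy().sum()
            nuc = df.filter(like="_nucleus").to_numpy().sum()
            wins += cyt > nuc
        assert wins >= 190  # pooled ratio > 1 in >= 95% of simulations

    def test_zero_depth_all_zero_and_fails_filter(self):
        cfg = SimConfig(mean_depth=0.0, low_expression_fraction=0.0)
        truth = GroundTruth(true_cytoplasmic_genes={"G1"})
        df = generate_counts(["G1", "G2"], truth, cfg, np.random.default_rng(1))
        assert (df.to_numpy() == 0).all()
        calls = classify_localization(
            FractionCounts(df, pd.Series(1e6, index=df.columns))
        )
        assert all(not c.passed_depth_filter for c in calls)

    def test_symmetric_fold_classifies_half(self):
        cfg = SimConfig(cyto_nuc_fold=1.0, low_expression_fraction=0.0, n_cell_lines=2)
        truth = GroundTruth(true_cytoplasmic_genes=set())
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(200)]
        df = generate_counts(genes, truth, cfg, rng)
        calls = classify_localization(
            FractionCounts(df, pd.Series(1e6, index=df.columns))
        )
        frac = sum(c.is_cytoplasmic for c in calls) / len(calls)
        assert 0.4 <= frac <= 0.6

    def test_localization_recovery_against_ground_truth(self, planted_dataset):
        cfg, out, truth = planted_dataset
        df = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene_id")
        calls = classify_localization(FractionCounts(df))
        lnc_calls = [c for c in calls if c.gene_id.startswith("SIMG") and c.total_reads >= 20]
        correct = sum(
            c.is_cytoplasmic == (c.gene_id in truth.true_cytoplasmic_genes)
            for c in lnc_calls
        )
        assert correct / len(lnc_calls) >= 0.9


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(clade_divergence={"primate": 0.3, "mammal": 0.1, "vertebrate": 0.4}),
            dict(background_gc=1.4),
            dict(planted_enrichment=-0.5),
            dict(planted_site_tier="bird"),
            dict(n_lncrna_genes=0),
            dict(n_species_per_clade={"primate": 0, "mammal": 2, "vertebrate": 2}),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
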