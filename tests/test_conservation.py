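"""MAF indexing, per-site intactness, and clade-tier assignment."""

import pytest

from lncmir.conservation import (
    CladeTable,
    ConservationConfig,
    call_site_conservation,
    load_maf,
    read_clade_table,
    stratify_sites,
)
from lncmir.seeds import SeedFamily, scan_transcript, seed_to_patterns

from conftest import make_transcript


def let7_site_on_reference(genome_offset=100):
    """Site built by scanning the reference transcript of the maf_bundle."""
    t = make_transcript("GGCTACCTCAGGTTTTTTTT", start=genome_offset)
    fam = SeedFamily("let-7", "GAGGUAG", "conserved")
    sites = scan_transcript(t, seed_to_patterns(fam))
    return next(s for s in sites if s.site_type == "8mer")


def write_maf(path, rows, start=100, src_size=200):
    lines = ["##maf version=1", "", "a score=0"]
    for sp, seq in rows.items():
        size = len(seq.replace("-", ""))
        lines.append(f"s {sp}.chr1 {start} {size} + {src_size} {seq}")
    lines.append("")
    path.write_text("\n".join(lines))
    return path


class TestMafIndex:
    def test_query_returns_equal_length_gapped_rows(self, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        index = load_maf(maf_bundle["maf"], clades)
        got = index.query("chr1", 100, 108)
        assert got is not None and len(got) == 14
        assert len({len(s) for s in got.values()}) == 1

    def test_query_outside_blocks_is_none(self, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        index = load_maf(maf_bundle["maf"], clades)
        assert index.query("chr1", 0, 8) is None
        assert index.query("chr2", 100, 108) is None
        assert index.query("chr1", 115, 125) is None  # partial coverage

    def test_reference_row_validated_against_fasta(self, maf_bundle, tmp_path):
        clades = read_clade_table(maf_bundle["clades"])
        bad = write_maf(
            tmp_path / "bad.maf",
            {"prim01": "AAAAAAAAAA", "vert01": "AAAAAAAAAA"},
            start=100,
        )
        with pytest.raises(ValueError, match="chr1:100"):
            load_maf(bad, clades, fasta=maf_bundle["fasta"])

    def test_unmapped_species_fails_by_name(self, maf_bundle, tmp_path):
        clades = read_clade_table(maf_bundle["clades"])
        bad = write_maf(
            tmp_path / "bad.maf", {"prim01": "ACGTACGT", "martian": "ACGTACGT"}
        )
        with pytest.raises(ValueError, match="martian"):
            load_maf(bad, clades)


class TestTierCalls:
    def test_mammal_tier_from_threshold_rule(self, maf_bundle):
        # intact: reference + the other primate + 4/5 mammals; all 7
        # non-mammal vertebrates broken. Fractions count non-reference
        # species: primate 1/1, mammal 5/6 pass, vertebrate 5/13 fails at
        # min_fraction 0.5
        clades = read_clade_table(maf_bundle["clades"])
        index = load_maf(maf_bundle["maf"], clades, fasta=maf_bundle["fasta"])
        call = call_site_conservation(let7_site_on_reference(), index, clades)
        assert call.tier == "mammal"
        assert call.fractions["primate"] == 1.0
        assert call.fractions["mammal"] == pytest.approx(5 / 6)
        assert call.fractions["vertebrate"] == pytest.approx(5 / 13)

    def test_reference_only_is_tier_none(self, tmp_path, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        intact = "GGCTACCTCAGGTTTTTTTT"
        broken = "GGCAACCACAGGTTTTTTTT"
        rows = {"prim01": intact, "prim02": broken, "mamm01": broken, "vert01": broken}
        index = load_maf(write_maf(tmp_path / "m.maf", rows), clades)
        call = call_site_conservation(let7_site_on_reference(), index, clades)
        assert call.tier == "none" and call.species_intact == {"prim01"}

    def test_all_species_intact_is_vertebrate(self, tmp_path, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        intact = "GGCTACCTCAGGTTTTTTTT"
        rows = {sp: intact for sp in clades.species}
        index = load_maf(write_maf(tmp_path / "m.maf", rows), clades)
        call = call_site_conservation(let7_site_on_reference(), index, clades)
        assert call.tier == "vertebrate"
        assert call.fractions == {"primate": 1.0, "mammal": 1.0, "vertebrate": 1.0}

    def test_uncovered_site_is_tier_none(self, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        index = load_maf(maf_bundle["maf"], clades)
        site = let7_site_on_reference(genome_offset=150)  # outside the block
        call = call_site_conservation(site, index, clades)
        assert call.tier == "none" and not call.species_intact

    def test_species_gap_within_site_breaks_intactness(self, tmp_path, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        rows = {
            "prim01": "GGCTACCTCAGGTTTTTTTT",
            "prim02": "GGCTAC-TCAGGTTTTTTTT",  # deletion inside the 8mer
        }
        index = load_maf(write_maf(tmp_path / "m.maf", rows), clades)
        call = call_site_conservation(
            let7_site_on_reference(), index, clades,
            ConservationConfig(min_fraction=0.5),
        )
        assert "prim02" not in call.species_intact

    def test_reference_insertion_gap_breaks_site_for_everyone(self, tmp_path, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        rows = {
            "prim01": "GGCTACC-TCAGGTTTTTTTT",  # gap column inside the site
            "prim02": "GGCTACCATCAGGTTTTTTTT",
        }
        index = load_maf(write_maf(tmp_path / "m.maf", rows), clades)
        call = call_site_conservation(let7_site_on_reference(), index, clades)
        assert call.tier == "none" and not call.species_intact

    def test_raising_min_fraction_never_raises_tier(self, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        index = load_maf(maf_bundle["maf"], clades)
        site = let7_site_on_reference()
        order = {"none": -1, "primate": 0, "mammal": 1, "vertebrate": 2}
        tiers = [
            call_site_conservation(
                site, index, clades, ConservationConfig(min_fraction=f)
            ).tier
            for f in (0.3, 0.5, 0.8, 1.0)
        ]
        assert all(order[a] >= order[b] for a, b in zip(tiers, tiers[1:]))


class TestStratify:
    def _site_with_tier(self, tier, site_type="8mer"):
        site = let7_site_on_reference()
        site.site_type = site_type
        from lncmir.conservation import ConservationCall

        site.conservation = ConservationCall(tier=tier)
        return site

    def test_nested_counting(self):
        counts = stratify_sites([self._site_with_tier("vertebrate")])
        assert counts[("primate", "8mer")] == 1
        assert counts[("mammal", "8mer")] == 1
        assert counts[("vertebrate", "8mer")] == 1

    def test_primate_only_site(self):
        counts = stratify_sites([self._site_with_tier("primate")])
        assert counts[("primate", "8mer")] == 1
        assert counts[("mammal", "8mer")] == 0
        assert counts[("vertebrate", "8mer")] == 0

    def test_empty_and_monotone(self):
        counts = stratify_sites([])
        assert set(counts.values()) == {0}
        sites = [
            self._site_with_tier(t, st)
            for t in ("primate", "mammal", "mammal", "vertebrate", "none")
            for st in ("8mer", "7mer-m8")
        ]
        counts = stratify_sites(sites)
        for st in ("8mer", "7mer-m8"):
            assert (
                counts[("primate", st)]
                >= counts[("mammal", st)]
                >= counts[("vertebrate", st)]
            )


class TestCladeTable:
    def test_reference_must_be_primate(self):
        with pytest.raises(ValueError, match="reference"):
            CladeTable(clade_of={"x": "mammal"}, reference="x")

    def test_nested_sets(self, maf_bundle):
        clades = read_clade_table(maf_bundle["clades"])
        assert clades.nested("primate") < clades.nested("mammal") < clades.nested(
            "vertebrate"
        )
        assert clades.reference in clades.nested("primate")
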