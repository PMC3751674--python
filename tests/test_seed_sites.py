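"""Seed pattern expansion, transcript scanning, and genome mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncmir.models import TranscriptModel, reverse_complement
from lncmir.seeds import (
    SITE_TYPES,
    SeedFamily,
    dedupe_gene_level,
    scan_transcript,
    seed_to_patterns,
)

from conftest import make_transcript

seeds_st = st.text(alphabet="ACGU", min_size=7, max_size=7)


def brute_force_scan(seq: str, patterns) -> set[tuple[str, int, str]]:
    """Position-by-position oracle with the same per-locus best-type rule."""
    raw = set()
    for p in patterns:
        for i in range(len(seq) - len(p.match_dna) + 1):
            if seq[i : i + len(p.match_dna)] == p.match_dna:
                raw.add((p.family_name, i, p.site_type))
    out = set()
    for fam, i, st_ in raw:
        if st_ == "7mer-m8" and (fam, i, "8mer") in raw:
            continue
        if st_ == "7mer-A1" and (
            (fam, i - 1, "8mer") in raw
            or (fam, i, "8mer") in raw
            or (fam, i, "7mer-m8") in raw
        ):
            continue
        out.add((fam, i, st_))
    return out


class TestPatterns:
    def test_let7_patterns(self, let7):
        by_type = {p.site_type: p.match_dna for p in seed_to_patterns(let7)}
        assert by_type == {
            "8mer": "CTACCTCA",
            "7mer-m8": "CTACCTC",
            "7mer-A1": "TACCTCA",
        }

    def test_poly_a_seed(self):
        by_type = {
            p.site_type: p.match_dna
            for p in seed_to_patterns(SeedFamily("f", "AAAAAAA"))
        }
        assert by_type == {
            "8mer": "TTTTTTTA",
            "7mer-m8": "TTTTTTT",
            "7mer-A1": "TTTTTTA",
        }

    @given(seed=seeds_st)
    @settings(max_examples=50, derandomize=True)
    def test_structure_invariants(self, seed):
        by_type = {
            p.site_type: p.match_dna for p in seed_to_patterns(SeedFamily("f", seed))
        }
        assert set(by_type) == set(SITE_TYPES)
        assert by_type["8mer"] == by_type["7mer-m8"] + "A"
        assert by_type["8mer"].endswith("A") and by_type["7mer-A1"].endswith("A")
        assert len(by_type["8mer"]) == 8 and len(by_type["7mer-m8"]) == 7

    def test_invalid_seed_rejected(self):
        with pytest.raises(ValueError):
            SeedFamily("f", "ACGTACG")  # T is not RNA
        with pytest.raises(ValueError):
            SeedFamily("f", "ACGACG")


class TestScan:
    def test_8mer_found_and_7mers_suppressed(self, let7):
        t = make_transcript("AACTACCTCAGG")
        sites = scan_transcript(t, seed_to_patterns(let7))
        assert [(s.site_type, s.transcript_pos) for s in sites] == [("8mer", 2)]

    def test_7mer_m8_without_downstream_A(self, let7):
        t = make_transcript("CTACCTCG")
        sites = scan_transcript(t, seed_to_patterns(let7))
        assert [(s.site_type, s.transcript_pos) for s in sites] == [("7mer-m8", 0)]

    def test_no_match(self, let7):
        t = make_transcript("GGGGGGGGGGGGGGGGGGGG")
        assert scan_transcript(t, seed_to_patterns(let7)) == []

    def test_overlapping_occurrences_reported(self):
        fam = SeedFamily("poly", "UUUUUUU")  # 7mer-m8 AAAAAAA, 8mer AAAAAAAA
        t = make_transcript("AAAAAAAAAA")  # 10 A's
        sites = scan_transcript(t, seed_to_patterns(fam))
        eights = [s.transcript_pos for s in sites if s.site_type == "8mer"]
        assert eights == [0, 1, 2]  # every window with a downstream A
        # the trailing poly-A window with no room for the 8mer stays a 7mer-m8
        assert [(s.site_type, s.transcript_pos) for s in sites if s.site_type != "8mer"] == [
            ("7mer-m8", 3)
        ]

    @given(
        seq=st.text(alphabet="ACGT", min_size=20, max_size=60),
        seeds=st.lists(seeds_st, min_size=1, max_size=3, unique=True),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, seq, seeds):
        patterns = []
        for i, s in enumerate(seeds):
            patterns.extend(seed_to_patterns(SeedFamily(f"f{i}", s)))
        t = make_transcript(seq)
        got = {
            (s.family_name, s.transcript_pos, s.site_type)
            for s in scan_transcript(t, patterns)
        }
        assert got == brute_force_scan(seq, patterns)


class TestGenomeMapping:
    def test_plus_strand_position(self, let7):
        t = make_transcript("AACTACCTCAGG", start=100)
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        assert site.genome_pos == 102
        assert site.genome_intervals == [(102, 110)]

    def test_minus_strand_equals_scanning_revcomp(self, let7):
        genomic = "CCTGAGGTAGTT"  # revcomp contains CTACCTCA at offset 2
        t = TranscriptModel(
            transcript_id="T1",
            gene_id="G1",
            chrom="chr1",
            strand="-",
            exons=[(100, 112)],
            spliced_seq=reverse_complement(genomic),
        )
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        assert site.site_type == "8mer" and site.transcript_pos == 2
        # transcript 5'-most base of the site maps near the genomic right end
        assert site.genome_pos == 112 - 1 - 2
        assert site.genome_intervals == [(102, 110)]
        assert reverse_complement(genomic[2:10]) == site.match_dna

    def test_junction_spanning_site(self, let7):
        # exon1 supplies AACTA, exon2 supplies CCTCAGG: site crosses junction
        t = TranscriptModel(
            transcript_id="T1",
            gene_id="G1",
            chrom="chr1",
            strand="+",
            exons=[(0, 5), (50, 57)],
            spliced_seq="AACTACCTCAGG",
        )
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        assert site.transcript_pos == 2
        assert site.genome_pos == 2
        assert site.genome_intervals == [(2, 5), (50, 55)]

    def test_dedupe_gene_level_collapses_shared_sites(self, let7):
        t1 = make_transcript("AACTACCTCAGG", transcript_id="T1", start=100)
        t2 = make_transcript("AACTACCTCAGG", transcript_id="T2", start=100)
        patterns = seed_to_patterns(let7)
        sites = scan_transcript(t1, patterns) + scan_transcript(t2, patterns)
        assert len(dedupe_gene_level(sites)) == 1


class TestRegions:
    def test_region_by_five_prime_base(self, let7):
        regions = {"UTR5": [(0, 3)], "CDS": [(3, 8)], "UTR3": [(8, 12)]}
        t = make_transcript("AACTACCTCAGG", regions=regions)
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        # site starts at 2 (UTR5) though it extends through CDS into UTR3
        assert site.region == "UTR5"

    def test_boundary_start_on_last_cds_base(self, let7):
        regions = {"CDS": [(0, 3)], "UTR3": [(3, 12)]}
        t = make_transcript("AACTACCTCAGG", regions=regions)
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        assert site.transcript_pos == 2 and site.region == "CDS"

    def test_lncrna_site(self, let7):
        t = make_transcript("AACTACCTCAGG")
        (site,) = scan_transcript(t, seed_to_patterns(let7))
        assert site.region == "LNC"
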