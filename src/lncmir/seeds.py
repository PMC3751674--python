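"""MicroRNA seed families, site patterns, and transcript scanning.

A seed is microRNA positions 2-8 (7 nt, RNA alphabet). The three canonical
site types, in decreasing stringency, are:

* ``8mer``    — perfect match to positions 2-8 followed by an A opposite
  microRNA position 1 (8 nt in the target),
* ``7mer-m8`` — perfect match to positions 2-8 (7 nt),
* ``7mer-A1`` — perfect match to positions 2-7 plus the position-1 A (7 nt).

Patterns are converted to DNA at build time and matched exactly against the
sense-strand spliced transcript sequence. When an 8mer matches, the 7mer
matches it contains are suppressed so that each locus carries its single best
site type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .models import TranscriptModel, reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .conservation import ConservationCall

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}  # lower = better
_SEED_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class SeedFamily:
    """A microRNA family: name, 7-nt seed (RNA), and conservation class."""

    family_name: str
    seed: str
    conservation_class: str = "conserved"

    def __post_init__(self) -> None:
        if len(self.seed) != 7 or not set(self.seed) <= _SEED_ALPHABET:
            raise ValueError(
                f"seed of {self.family_name} must be 7 nt over ACGU, got {self.seed!r}"
            )


@dataclass(frozen=True)
class SitePattern:
    """A DNA string to locate in sense transcript sequence for one site type."""

    family_name: str
    site_type: str
    match_dna: str


@dataclass
class TargetSite:
    """One seed match in a transcript, mapped back to the genome.

    ``genome_pos`` is the genomic coordinate (0-based) of the site's 5'-most
    base in transcript orientation; ``genome_intervals`` cover all site bases
    in ascending genomic order (more than one interval when the site spans a
    splice junction).
    """

    gene_id: str
    transcript_id: str
    family_name: str
    site_type: str
    transcript_pos: int
    genome_chrom: str
    genome_pos: int
    strand: str
    genome_intervals: list[tuple[int, int]] = field(default_factory=list)
    match_dna: str = ""
    region: str = ""
    conservation: "ConservationCall | None" = None

    @property
    def length(self) -> int:
        return 8 if self.site_type == "8mer" else 7


def seed_to_patterns(family: SeedFamily) -> list[SitePattern]:
    """Expand a seed into its three site patterns (DNA, sense-strand target).

    The 7mer-m8 is the reverse complement of the full seed; the 8mer appends
    the position-1 A; the 7mer-A1 is the reverse complement of seed positions
    1-6 (microRNA positions 2-7) plus the A.
    """
    seed_dna = family.seed.replace("U", "T")
    m8 = reverse_complement(seed_dna)
    return [
        SitePattern(family.family_name, "8mer", m8 + "A"),
        SitePattern(family.family_name, "7mer-m8", m8),
        SitePattern(family.family_name, "7mer-A1", reverse_complement(seed_dna[:6]) + "A"),
    ]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)  # overlapping occurrences included
    return hits


def scan_transcript(
    t: TranscriptModel, patterns: list[SitePattern]
) -> list[TargetSite]:
    """All exact pattern occurrences in the spliced sequence, best-type per locus.

    An 8mer hit at position p suppresses the same family's 7mer-m8 at p and
    7mer-A1 at p+1 (the matches it physically contains). Transcript positions
    are mapped to genome coordinates through the exon structure, strand-aware;
    junction-spanning sites keep the genomic position of their 5'-most base in
    transcript orientation.
    """
    seq = t.spliced_seq
    by_family: dict[str, dict[str, list[int]]] = {}
    for p in patterns:
        by_family.setdefault(p.family_name, {})[p.site_type] = _find_all(
            seq, p.match_dna
        )
    sites: list[TargetSite] = []
    for family, hits in by_family.items():
        eight = hits.get("8mer", [])
        eight_set = set(eight)
        picked: list[tuple[int, str]] = [(p, "8mer") for p in eight]
        for p in hits.get("7mer-m8", []):
            if p not in eight_set:
                picked.append((p, "7mer-m8"))
        m8_set = set(hits.get("7mer-m8", []))
        for p in hits.get("7mer-A1", []):
            if p - 1 in eight_set:
                continue  # contained in an 8mer
            if p in eight_set or p in m8_set:
                continue  # the position already carries a better site type
            picked.append((p, "7mer-A1"))
        for pos, site_type in picked:
            length = 8 if site_type == "8mer" else 7
            gpositions = t.genome_positions(pos, length)
            intervals = t.genome_intervals(pos, length)
            sites.append(
                TargetSite(
                    gene_id=t.gene_id,
                    transcript_id=t.transcript_id,
                    family_name=family,
                    site_type=site_type,
                    transcript_pos=pos,
                    genome_chrom=t.chrom,
                    genome_pos=gpositions[0],
                    strand=t.strand,
                    genome_intervals=intervals,
                    match_dna=seq[pos : pos + length],
                )
            )
    sites.sort(key=lambda s: (s.family_name, s.transcript_pos, _SITE_RANK[s.site_type]))
    for s in sites:
        s.region = assign_region(s, t)
    return sites


def assign_region(site: TargetSite, t: TranscriptModel) -> str:
    """UTR5/CDS/UTR3 by the site's 5'-most transcript base; LNC when the
    transcript carries no region annotation."""
    if not t.regions:
        return "LNC"
    for label in ("UTR5", "CDS", "UTR3"):
        for start, end in t.regions.get(label, []):
            if start <= site.transcript_pos < end:
                return label
    return "LNC"


def dedupe_gene_level(sites: list[TargetSite]) -> list[TargetSite]:
    """Collapse isoform-shared sites: one site per (gene, genomic position,
    family, site type)."""
    seen: dict[tuple, TargetSite] = {}
    for s in sites:
        key = (s.gene_id, s.genome_chrom, s.genome_pos, s.family_name, s.site_type)
        if key not in seen:
            seen[key] = s
    return sorted(
        seen.values(), key=lambda s: (s.gene_id, s.genome_pos, s.family_name)
    )


def read_seed_table(path: str | Path) -> list[SeedFamily]:
    """TSV with columns family, seed_7mer, conservation_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family", "seed_7mer", "conservation_class"}
    if not required <= set(df.columns):
        raise ValueError(f"seed table must have columns {sorted(required)}")
    return [
        SeedFamily(row.family, row.seed_7mer, row.conservation_class)
        for row in df.itertuples(index=False)
    ]


def write_seed_table(families: list[SeedFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tseed_7mer\tconservation_class\n")
        for f in families:
            fh.write(f"{f.family_name}\t{f.seed}\t{f.conservation_class}\n")


def write_sites_bed(sites: list[TargetSite], path: str | Path) -> None:
    """BED6+3: chrom, start, end, family|site_type, 0, strand, gene,
    transcript, region (start/end span the whole site in genome space)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.genome_chrom, x.genome_intervals[0][0])):
            start = s.genome_intervals[0][0]
            end = s.genome_intervals[-1][1]
            fh.write(
                f"{s.genome_chrom}\t{start}\t{end}\t{s.family_name}|{s.site_type}"
                f"\t0\t{s.strand}\t{s.gene_id}\t{s.transcript_id}\t{s.region}\n"
            )
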