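"""Clade-tier conservation calls from a multiple alignment (MAF).

A target site is "intact" in a species when that species' aligned sequence
over the site's reference columns equals the site's match string exactly —
no substitutions and no gaps in either the reference or the species row
within the site. Sites are then assigned the deepest nested clade tier
(primate ⊂ mammal ⊂ vertebrate) in which the fraction of intact species
reaches the configured threshold, requiring every shallower clade to pass
as well.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .models import reverse_complement
from .seeds import SITE_TYPES, TargetSite

#: nested clade tiers, shallowest to deepest
CLADE_ORDER = ("primate", "mammal", "vertebrate")
_CLADE_DEPTH = {c: i for i, c in enumerate(CLADE_ORDER)}


@dataclass
class CladeTable:
    """Species → exclusive clade group, with derived nested tier sets.

    ``clade_of`` labels each species by its exclusive group (primate,
    non-primate placental mammal, or non-mammal vertebrate, stored as
    primate/mammal/vertebrate). The nested sets used for tier calls are
    cumulative: the mammal tier includes the primates, the vertebrate tier
    includes everything.
    """

    clade_of: dict[str, str]
    reference: str

    def __post_init__(self) -> None:
        bad = {c for c in self.clade_of.values() if c not in CLADE_ORDER}
        if bad:
            raise ValueError(f"unknown clades: {sorted(bad)}")
        if self.clade_of.get(self.reference) != "primate":
            raise ValueError("reference species must be present and a primate")

    def nested(self, tier: str) -> set[str]:
        depth = _CLADE_DEPTH[tier]
        return {
            sp
            for sp, c in self.clade_of.items()
            if _CLADE_DEPTH[c] <= depth
        }

    @property
    def species(self) -> set[str]:
        return set(self.clade_of)


def read_clade_table(path: str | Path, reference: str | None = None) -> CladeTable:
    """TSV with columns species, clade; reference defaults to the first
    primate listed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species", "clade"} <= set(df.columns):
        raise ValueError("clade table must have columns species, clade")
    clade_of = dict(zip(df["species"], df["clade"]))
    if reference is None:
        primates = [s for s, c in clade_of.items() if c == "primate"]
        if not primates:
            raise ValueError("clade table lists no primate for reference")
        reference = primates[0]
    return CladeTable(clade_of=clade_of, reference=reference)


def write_clade_table(table: CladeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tclade\n")
        # reference first so round-tripping preserves the default reference
        ordered = sorted(
            table.clade_of, key=lambda s: (s != table.reference, s)
        )
        for sp in ordered:
            fh.write(f"{sp}\t{table.clade_of[sp]}\n")


@dataclass
class ConservationConfig:
    """Thresholds for tier calls.

    ``min_fraction`` is the fraction of aligned clade species that must carry
    the intact match (0.5 by default); ``require_reference`` demands the
    reference row itself matches; ``absent_counts_against`` keeps species
    missing from a block in the clade denominator instead of excluding them.
    """

    min_fraction: float = 0.5
    require_reference: bool = True
    absent_counts_against: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass
class ConservationCall:
    species_intact: set[str] = field(default_factory=set)
    tier: str = "none"
    fractions: dict[str, float] = field(default_factory=dict)


class _Block:
    __slots__ = ("start", "end", "rows", "ref_cols")

    def __init__(self, start: int, end: int, rows: dict[str, str], ref_cols: np.ndarray):
        self.start = start
        self.end = end
        self.rows = rows  # species -> gapped aligned string
        self.ref_cols = ref_cols  # reference position offset -> column index


class MafIndex:
    """Per-chromosome interval index over MAF blocks, anchored on the
    reference species. Supports querying a reference interval for the aligned
    (gapped) substrings of every species in the covering block."""

    def __init__(self, reference: str):
        self.reference = reference
        self._blocks: dict[str, list[_Block]] = {}
        self._starts: dict[str, list[int]] = {}

    def add_block(self, chrom: str, block: _Block) -> None:
        self._blocks.setdefault(chrom, []).append(block)

    def finalize(self) -> None:
        for chrom in self._blocks:
            self._blocks[chrom].sort(key=lambda b: b.start)
            self._starts[chrom] = [b.start for b in self._blocks[chrom]]

    def query(self, chrom: str, start: int, end: int) -> dict[str, str] | None:
        """Aligned substrings over reference columns [start, end), gaps
        preserved, or None when no single block fully covers the interval."""
        blocks = self._blocks.get(chrom)
        if not blocks:
            return None
        i = bisect.bisect_right(self._starts[chrom], start) - 1
        if i < 0:
            return None
        b = blocks[i]
        if not (b.start <= start and end <= b.end):
            return None
        c0 = b.ref_cols[start - b.start]
        c1 = b.ref_cols[end - 1 - b.start] + 1
        return {sp: row[c0:c1] for sp, row in b.rows.items()}


def load_maf(
    maf: str | Path,
    clades: CladeTable,
    fasta: str | Path | None = None,
) -> MafIndex:
    """Parse a MAF into a reference-anchored index.

    Row names follow the ``species.chrom`` convention. Every species must be
    present in the clade table; when ``fasta`` is given, reference rows are
    validated against the genome and a mismatch raises ``ValueError`` naming
    the coordinates.
    """
    genome = None
    if fasta is not None:
        from pyfaidx import Fasta

        genome = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    index = MafIndex(clades.reference)
    with open(maf) as fh:
        for k, aln in enumerate(AlignIO.parse(fh, "maf")):
            rows: dict[str, str] = {}
            ref_chrom = None
            ref_start = None
            ref_seq = None
            for rec in aln:
                if "." not in rec.id:
                    raise ValueError(
                        f"MAF block {k}: row {rec.id!r} not named species.chrom"
                    )
                species, chrom = rec.id.split(".", 1)
                if species not in clades.species:
                    raise ValueError(
                        f"MAF block {k}: species {species!r} missing from clade table"
                    )
                rows[species] = str(rec.seq).upper()
                if species == clades.reference:
                    ref_chrom = chrom
                    ref_start = rec.annotations["start"]
                    ref_seq = rows[species]
            if ref_seq is None:
                raise ValueError(f"MAF block {k}: no reference-species row")
            gapless = ref_seq.replace("-", "")
            if genome is not None:
                expect = genome[ref_chrom][ref_start : ref_start + len(gapless)]
                if gapless != expect:
                    raise ValueError(
                        f"MAF block {k}: reference row disagrees with FASTA at "
                        f"{ref_chrom}:{ref_start}-{ref_start + len(gapless)}"
                    )
            mask = np.frombuffer(ref_seq.encode(), dtype=np.uint8) != ord("-")
            ref_cols = np.flatnonzero(mask)
            index.add_block(
                ref_chrom,
                _Block(ref_start, ref_start + len(gapless), rows, ref_cols),
            )
    index.finalize()
    return index


def _intact_species(site: TargetSite, index: MafIndex) -> tuple[set[str], set[str]] | None:
    """(intact species, aligned species) over the site, or None if any part of
    the site is unalignable."""
    pieces: list[dict[str, str]] = []
    for start, end in site.genome_intervals:
        got = index.query(site.genome_chrom, start, end)
        if got is None:
            return None
        pieces.append(got)
    aligned = set(pieces[0])
    for p in pieces[1:]:
        aligned &= set(p)
    # expected genomic-orientation string over the intervals, ascending order
    expect = (
        site.match_dna
        if site.strand == "+"
        else reverse_complement(site.match_dna)
    )
    ref_row = "".join(p[index.reference] for p in pieces)
    if "-" in ref_row:
        # insertion columns inside the site: a gap in the reference row means
        # no species (reference included) is gaplessly intact over the site
        return set(), aligned
    intact = set()
    for sp in aligned:
        s = "".join(p[sp] for p in pieces)
        if s == expect:
            intact.add(sp)
    return intact, aligned


def call_site_conservation(
    site: TargetSite,
    index: MafIndex,
    clades: CladeTable,
    cfg: ConservationConfig | None = None,
) -> ConservationCall:
    """Per-site conservation: intact species set, per-clade fractions, tier.

    The expected string per species is the reference row itself (the site is
    defined on the reference genome), so a species is intact iff it aligns
    gaplessly and identically over the site's reference columns. Sites not
    covered by the alignment get tier "none".
    """
    cfg = cfg or ConservationConfig()
    got = _intact_species(site, index)
    call = ConservationCall()
    if got is None:
        return call
    intact, aligned = got
    call.species_intact = intact
    if cfg.require_reference and index.reference not in intact:
        # reference row broken (or gapped) over the site
        for tier in CLADE_ORDER:
            call.fractions[tier] = 0.0
        return call
    # The reference trivially carries its own site, so clade fractions are
    # computed over non-reference species; the reference is handled by the
    # require_reference gate above. A clade with no non-reference species
    # aligned passes vacuously.
    tier_called = "none"
    passing = True
    for tier in CLADE_ORDER:
        clade_species = clades.nested(tier) - {index.reference}
        denom_species = (
            clade_species if cfg.absent_counts_against else clade_species & aligned
        )
        n = len(denom_species)
        frac = len(intact & denom_species) / n if n else 1.0
        call.fractions[tier] = frac
        if passing and frac >= cfg.min_fraction:
            tier_called = tier
        else:
            passing = False
    call.tier = tier_called
    return call


def stratify_sites(
    sites: list[TargetSite],
    tiers: tuple[str, ...] = CLADE_ORDER,
    site_types: tuple[str, ...] = SITE_TYPES,
) -> dict[tuple[str, str], int]:
    """Cumulative (tier, site_type) counts: a mammal-tier site counts in the
    primate and mammal strata; counts are monotone non-increasing with
    stringency within each site type."""
    counts = {(tier, st): 0 for tier in tiers for st in site_types}
    for s in sites:
        if s.conservation is None or s.conservation.tier == "none":
            continue
        depth = _CLADE_DEPTH[s.conservation.tier]
        for tier in tiers:
            if _CLADE_DEPTH[tier] <= depth and (tier, s.site_type) in counts:
                counts[(tier, s.site_type)] += 1
    return counts


def write_conserved_sites_bed(sites: list[TargetSite], path: str | Path) -> None:
    """Site BED augmented with tier and per-clade intact fractions."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.genome_chrom, x.genome_intervals[0][0])):
            call = s.conservation or ConservationCall()
            fr = ",".join(
                f"{tier}:{call.fractions.get(tier, 0.0):.2f}" for tier in CLADE_ORDER
            )
            start = s.genome_intervals[0][0]
            end = s.genome_intervals[-1][1]
            fh.write(
                f"{s.genome_chrom}\t{start}\t{end}\t{s.family_name}|{s.site_type}"
                f"\t0\t{s.strand}\t{s.gene_id}\t{call.tier}\t{fr}\n"
            )
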