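"""Synthetic multi-species datasets with planted, tier-conserved target sites.

Emits all five pipeline inputs — reference genome FASTA, multi-species MAF,
GENCODE-dialect GTF, seed-family table, and a nuclear/cytoplasmic fraction
count matrix — with known ground truth, so the whole pipeline can be exercised
and calibrated without external data.

The model is deliberately minimal:

* background sequence is i.i.d. with configurable GC content (default 0.41,
  human-like);
* the species tree is a star within each clade group: every non-reference
  species is an independently substituted copy of the reference, at a
  per-clade per-site substitution probability (conservation calls here are
  presence/absence per species, so a star suffices);
* genes are single-exon, laid out on one chromosome with a fixed intergenic
  spacing; coding transcripts carry UTR5/CDS/UTR3 regions;
* for each conserved seed family, round((e-1)·E) extra 8mer sites are written
  into host transcripts, where e is the requested enrichment factor and E is
  the analytic expected count of background sites reaching the planted
  conservation tier; planted sites are held invariant in all species of the
  planted tier's clades and broken (>= 2 substitutions) in deeper clades, so
  the expected observed-to-expected ratio at the planted stratum equals e.
  With e = 1 nothing is planted and the dataset is a null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .conservation import CLADE_ORDER, CladeTable, write_clade_table
from .models import GeneModel, reverse_complement
from .seeds import SeedFamily, seed_to_patterns, write_seed_table

_DNA = "ACGT"
_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RNA = "ACGU"
_CLADE_DEPTH = {c: i for i, c in enumerate(CLADE_ORDER)}

CHROM = "chr1"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``n_species_per_clade`` gives exclusive group sizes (primates, non-primate
    placental mammals, non-mammal vertebrates); the reference is the first
    primate and is emitted unmutated. ``clade_divergence`` is the per-site
    substitution probability for species of each group and must be monotone
    non-decreasing from primate to vertebrate. ``planted_enrichment`` is the
    target observed/expected factor for conserved 8mer sites at
    ``planted_site_tier``; 1.0 plants nothing (the null).
    """

    seed_rng: int = 1
    n_species_per_clade: dict[str, int] = dc_field(
        default_factory=lambda: {"primate": 3, "mammal": 4, "vertebrate": 8}
    )
    n_coding_genes: int = 30
    n_lncrna_genes: int = 60
    utr5_len: int = 150
    cds_len: int = 600
    utr3_len: int = 800
    lnc_len: int = 1000
    background_gc: float = 0.41
    clade_divergence: dict[str, float] = dc_field(
        default_factory=lambda: {"primate": 0.05, "mammal": 0.15, "vertebrate": 0.45}
    )
    planted_enrichment: float = 1.0
    planted_site_tier: str = "mammal"
    tier_min_fraction: float = 0.5
    n_seed_families_conserved: int = 87
    n_seed_families_nonconserved: int = 87
    cyto_bias_fraction: float = 0.5
    n_cell_lines: int = 7
    mean_depth: float = 100.0
    nb_dispersion: float = 0.1
    low_expression_fraction: float = 0.1
    cyto_nuc_fold: float = 4.0
    intergenic_spacing: int = 12_000

    def __post_init__(self) -> None:
        for clade in CLADE_ORDER:
            if self.n_species_per_clade.get(clade, 0) < 1:
                raise ValueError(f"need >= 1 species in clade {clade}")
            d = self.clade_divergence.get(clade)
            if d is None or not 0 <= d <= 0.5:
                raise ValueError(f"divergence for {clade} must be in [0, 0.5]")
        divs = [self.clade_divergence[c] for c in CLADE_ORDER]
        if not all(a <= b for a, b in zip(divs, divs[1:])):
            raise ValueError("divergence must be non-decreasing primate->vertebrate")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must be in [0, 1]")
        if self.planted_enrichment < 0:
            raise ValueError("planted_enrichment must be >= 0")
        if self.planted_site_tier not in CLADE_ORDER:
            raise ValueError(f"planted_site_tier must be one of {CLADE_ORDER}")
        for name in (
            "n_coding_genes",
            "n_lncrna_genes",
            "n_seed_families_conserved",
            "n_cell_lines",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def base_probs(self) -> np.ndarray:
        gc = self.background_gc
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    @property
    def species_of_clade(self) -> dict[str, list[str]]:
        prefixes = {"primate": "prim", "mammal": "mamm", "vertebrate": "vert"}
        return {
            clade: [
                f"{prefixes[clade]}{i:02d}"
                for i in range(1, self.n_species_per_clade[clade] + 1)
            ]
            for clade in CLADE_ORDER
        }

    @property
    def reference_species(self) -> str:
        return self.species_of_clade["primate"][0]

    @property
    def cell_lines(self) -> list[str]:
        return [f"cell{chr(ord('A') + i)}" for i in range(self.n_cell_lines)]


@dataclass
class PlantedSite:
    gene_id: str
    transcript_id: str
    transcript_pos: int
    family_name: str
    tier: str
    chrom: str = CHROM
    genome_start: int = 0
    strand: str = "+"
    pattern: str = ""


@dataclass
class GroundTruth:
    planted_sites: list[PlantedSite] = dc_field(default_factory=list)
    true_cytoplasmic_genes: set[str] = dc_field(default_factory=set)


@dataclass
class _SimGene:
    gene_id: str
    symbol: str
    kind: str  # "coding" | "lnc"
    strand: str
    start: int
    length: int
    sense: np.ndarray | None = None  # sense-strand base codes

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def transcript_id(self) -> str:
        return self.gene_id.replace("SIMG", "SIMT") + ".1"


def _codes_to_str(codes: np.ndarray) -> str:
    return _DNA_BYTES[codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def spontaneous_tier_prob(cfg: SimConfig, tier: str) -> float:
    """Probability that a background 8mer site on the reference reaches the
    cumulative conservation stratum ``tier`` by chance.

    A non-reference species of group c is intact with probability
    (1 - divergence_c)^8. Clade fractions follow the conservation caller:
    they are taken over non-reference species (the reference trivially
    carries its own site), and a clade with no non-reference species passes
    vacuously. Clade-pass events are evaluated exactly by enumerating
    binomial outcomes over the nested denominators.
    """
    q = {c: (1 - cfg.clade_divergence[c]) ** 8 for c in CLADE_ORDER}
    n_p = cfg.n_species_per_clade["primate"] - 1  # non-reference primates
    n_m = cfg.n_species_per_clade["mammal"]
    n_v = cfg.n_species_per_clade["vertebrate"]
    f = cfg.tier_min_fraction
    depth = _CLADE_DEPTH[tier]

    def passes(intact: int, denom: int) -> bool:
        return denom == 0 or intact / denom >= f

    pmf_p = stats.binom.pmf(np.arange(n_p + 1), n_p, q["primate"])
    pmf_m = stats.binom.pmf(np.arange(n_m + 1), n_m, q["mammal"])
    pmf_v = stats.binom.pmf(np.arange(n_v + 1), n_v, q["vertebrate"])
    total = 0.0
    for i in range(n_p + 1):
        if not passes(i, n_p):
            continue
        if depth == 0:
            total += pmf_p[i]
            continue
        for j in range(n_m + 1):
            if not passes(i + j, n_p + n_m):
                continue
            if depth == 1:
                total += pmf_p[i] * pmf_m[j]
                continue
            for k in range(n_v + 1):
                if not passes(i + j + k, n_p + n_m + n_v):
                    continue
                total += pmf_p[i] * pmf_m[j] * pmf_v[k]
    return float(total)


def _match_prob(pattern: str, probs: np.ndarray) -> float:
    p = 1.0
    for b in pattern:
        p *= probs[_DNA.index(b)]
    return float(p)


def _distinct_random_seeds(
    rng: np.random.Generator, n: int, taken: set[str]
) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        s = "".join(_RNA[i] for i in rng.integers(0, 4, size=7))
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def _make_families(cfg: SimConfig, rng: np.random.Generator) -> list[SeedFamily]:
    taken: set[str] = set()
    conserved = _distinct_random_seeds(rng, cfg.n_seed_families_conserved, taken)
    nonconserved = _distinct_random_seeds(rng, cfg.n_seed_families_nonconserved, taken)
    fams = [
        SeedFamily(f"simfam-c{i:03d}", s, "conserved")
        for i, s in enumerate(conserved, 1)
    ]
    fams += [
        SeedFamily(f"simfam-n{i:03d}", s, "nonconserved")
        for i, s in enumerate(nonconserved, 1)
    ]
    return fams


def _layout_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_SimGene]:
    coding_len = cfg.utr5_len + cfg.cds_len + cfg.utr3_len
    genes = []
    pos = cfg.intergenic_spacing
    k = 0
    for kind, n, length, prefix in (
        ("coding", cfg.n_coding_genes, coding_len, "PC"),
        ("lnc", cfg.n_lncrna_genes, cfg.lnc_len, "LNC"),
    ):
        for i in range(1, n + 1):
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _SimGene(
                    gene_id=f"SIMG{k:06d}",
                    symbol=f"{prefix}{i:04d}",
                    kind=kind,
                    strand=strand,
                    start=pos,
                    length=length,
                )
            )
            pos += length + cfg.intergenic_spacing
    return genes


def _plant_sites(
    cfg: SimConfig,
    genes: list[_SimGene],
    families: list[SeedFamily],
    rng: np.random.Generator,
) -> list[PlantedSite]:
    if cfg.planted_enrichment == 1.0:
        return []
    hosts = [g for g in genes if g.kind == "lnc"] or [
        g for g in genes if g.kind == "coding"
    ]
    host_len = hosts[0].length
    if host_len < 8:
        raise ValueError("transcript too short to host a site (< 8 nt)")
    n_positions = sum(g.length - 7 for g in hosts)
    p_tier = spontaneous_tier_prob(cfg, cfg.planted_site_tier)
    conserved = [f for f in families if f.conservation_class == "conserved"]
    eight_of = {
        f.family_name: next(p for p in seed_to_patterns(f) if p.site_type == "8mer")
        for f in conserved
    }
    n_plant_of = {
        f.family_name: round(
            (cfg.planted_enrichment - 1.0)
            * n_positions
            * _match_prob(eight_of[f.family_name].match_dna, cfg.base_probs)
            * p_tier
        )
        for f in conserved
    }
    # non-overlapping 8 nt windows bound the number of placeable sites
    capacity = sum((g.length - 8) // 8 + 1 for g in hosts)
    if sum(n_plant_of.values()) > capacity:
        raise ValueError(
            "impossible enrichment: planted sites would exceed sequence capacity "
            f"({sum(n_plant_of.values())} sites requested, {capacity} placeable)"
        )
    taken: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in hosts}
    planted: list[PlantedSite] = []
    for fam in conserved:
        eight = eight_of[fam.family_name]
        n_plant = n_plant_of[fam.family_name]
        attempts = 0
        placed = 0
        while placed < n_plant:
            attempts += 1
            if attempts > 1000 * max(n_plant, 1):
                raise ValueError(
                    "impossible enrichment: cannot place planted sites without "
                    "overlap (sequence capacity exceeded)"
                )
            g = hosts[int(rng.integers(len(hosts)))]
            pos = int(rng.integers(0, g.length - 7))
            if any(pos < e + 8 and s < pos + 8 for s, e in taken[g.gene_id]):
                continue
            taken[g.gene_id].append((pos, pos + 8))
            g.sense[pos : pos + 8] = [
                _DNA.index(b) for b in eight.match_dna
            ]
            if g.strand == "+":
                gstart = g.start + pos
            else:
                gstart = g.start + g.length - pos - 8
            planted.append(
                PlantedSite(
                    gene_id=g.gene_id,
                    transcript_id=g.transcript_id,
                    transcript_pos=pos,
                    family_name=fam.family_name,
                    tier=cfg.planted_site_tier,
                    genome_start=gstart,
                    strand=g.strand,
                    pattern=eight.match_dna,
                )
            )
            placed += 1
    return planted


def _write_fasta(path: Path, chrom: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def _gtf_attrs(gene: _SimGene, cfg: SimConfig, transcript: bool) -> str:
    gtype = "protein_coding" if gene.kind == "coding" else "lincRNA"
    parts = [f'gene_id "{gene.gene_id}"']
    if transcript:
        parts.append(f'transcript_id "{gene.transcript_id}"')
    parts.append(f'gene_type "{gtype}"')
    if transcript:
        parts.append(f'transcript_type "{gtype}"')
    parts.append(f'gene_name "{gene.symbol}"')
    return "; ".join(parts) + ";"


def _write_gtf(path: Path, genes: list[_SimGene], cfg: SimConfig) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s1, e1 = g.start + 1, g.end  # 1-based inclusive
            base = f"{CHROM}\tlncmir_sim"
            tail = f".\t{g.strand}\t."
            fh.write(f"{base}\tgene\t{s1}\t{e1}\t{tail}\t{_gtf_attrs(g, cfg, False)}\n")
            attrs = _gtf_attrs(g, cfg, True)
            for ft in ("transcript", "exon"):
                fh.write(f"{base}\t{ft}\t{s1}\t{e1}\t{tail}\t{attrs}\n")
            if g.kind == "coding":
                u5, cds = cfg.utr5_len, cfg.cds_len
                if g.strand == "+":
                    regions = [
                        ("five_prime_utr", g.start, g.start + u5),
                        ("CDS", g.start + u5, g.start + u5 + cds),
                        ("three_prime_utr", g.start + u5 + cds, g.end),
                    ]
                else:
                    regions = [
                        ("five_prime_utr", g.end - u5, g.end),
                        ("CDS", g.end - u5 - cds, g.end - u5),
                        ("three_prime_utr", g.start, g.end - u5 - cds),
                    ]
                for ft, s, e in regions:
                    fh.write(f"{base}\t{ft}\t{s + 1}\t{e}\t{tail}\t{attrs}\n")


def _mutated_block(
    ref: np.ndarray, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    out = ref.copy()
    if divergence > 0:
        mask = rng.random(len(ref)) < divergence
        n = int(mask.sum())
        if n:
            out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _enforce_planted(
    row: np.ndarray,
    ref: np.ndarray,
    offset: int,
    clade_depth: int,
    planted_depth: int,
    rng: np.random.Generator,
) -> None:
    """Restore a planted window in tier species; force >= 2 mismatches in
    deeper species. ``offset`` is the window start within the block."""
    window = slice(offset, offset + 8)
    if clade_depth <= planted_depth:
        row[window] = ref[window]
        return
    mismatches = int((row[window] != ref[window]).sum())
    while mismatches < 2:
        i = offset + int(rng.integers(8))
        if row[i] == ref[i]:
            row[i] = (ref[i] + int(rng.integers(1, 4))) % 4
            mismatches += 1


def _write_maf(
    path: Path,
    genes: list[_SimGene],
    genome_len: int,
    cfg: SimConfig,
    planted_by_gene: dict[str, list[PlantedSite]],
    rng: np.random.Generator,
) -> None:
    species_order = [
        (sp, clade)
        for clade in CLADE_ORDER
        for sp in cfg.species_of_clade[clade]
    ]
    planted_depth = _CLADE_DEPTH[cfg.planted_site_tier]
    with open(path, "w") as fh:
        alignments = []
        for g in genes:
            ref_block = g.sense if g.strand == "+" else np.flip(3 - g.sense)
            plant_offsets = [
                ps.genome_start - g.start for ps in planted_by_gene.get(g.gene_id, [])
            ]
            records = []
            for sp, clade in species_order:
                if sp == cfg.reference_species:
                    row = ref_block
                else:
                    row = _mutated_block(
                        ref_block, cfg.clade_divergence[clade], rng
                    )
                    for off in plant_offsets:
                        _enforce_planted(
                            row, ref_block, off, _CLADE_DEPTH[clade], planted_depth, rng
                        )
                records.append(
                    SeqRecord(
                        Seq(_codes_to_str(row)),
                        id=f"{sp}.{CHROM}",
                        annotations={
                            "start": g.start,
                            "size": g.length,
                            "strand": "+",
                            "srcSize": genome_len,
                        },
                    )
                )
            alignments.append(MultipleSeqAlignment(records))
        AlignIO.write(alignments, fh, "maf")


def generate_counts(
    genes: list[str] | list[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial fraction counts per gene x (cell line x fraction).

    Genes in ``truth.true_cytoplasmic_genes`` get an expected cytoplasm:nucleus
    ratio of ``cyto_nuc_fold`` : 1 per library; all others the inverse. A
    ``low_expression_fraction`` of genes is simulated at near-zero depth to
    exercise the downstream >= 20-read filter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed_rng)
    gene_ids = [g if isinstance(g, str) else g.gene_id for g in genes]
    r_disp = 1.0 / config.nb_dispersion if config.nb_dispersion > 0 else 1e9
    fold = config.cyto_nuc_fold
    columns = [
        f"{cell}_{fraction}"
        for cell in config.cell_lines
        for fraction in ("cytoplasm", "nucleus")
    ]
    data = np.zeros((len(gene_ids), len(columns)), dtype=np.int64)
    low = rng.random(len(gene_ids)) < config.low_expression_fraction
    for i, gid in enumerate(gene_ids):
        depth = 0.5 if low[i] else config.mean_depth
        if gid in truth.true_cytoplasmic_genes:
            mu_c, mu_n = depth * fold / (1 + fold), depth / (1 + fold)
        else:
            mu_c, mu_n = depth / (1 + fold), depth * fold / (1 + fold)
        for j, col in enumerate(columns):
            mu = mu_c if col.endswith("_cytoplasm") else mu_n
            p = r_disp / (r_disp + mu)
            data[i, j] = rng.negative_binomial(r_disp, p)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=columns)


def generate_dataset(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Write genome.fa, alignment.maf, annotation.gtf, seeds.tsv, clades.tsv
    and counts.tsv under ``out_dir``; return the ground truth.

    Byte-identical outputs for identical configs (single RNG stream seeded
    from ``seed_rng``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed_rng)
    if config.lnc_len < 8 or config.utr3_len < 8:
        raise ValueError("transcript too short to host a site (< 8 nt)")

    genes = _layout_genes(config, rng)
    for g in genes:
        g.sense = _random_codes(rng, g.length, config.base_probs)
    families = _make_families(config, rng)
    planted = _plant_sites(config, genes, families, rng)

    genome_len = genes[-1].end + config.intergenic_spacing
    parts: list[str] = []
    cursor = 0
    for g in genes:
        parts.append(_codes_to_str(_random_codes(rng, g.start - cursor, config.base_probs)))
        block = g.sense if g.strand == "+" else np.flip(3 - g.sense)
        parts.append(_codes_to_str(block))
        cursor = g.end
    parts.append(_codes_to_str(_random_codes(rng, genome_len - cursor, config.base_probs)))
    genome = "".join(parts)

    _write_fasta(out / "genome.fa", CHROM, genome)
    _write_gtf(out / "annotation.gtf", genes, config)
    planted_by_gene: dict[str, list[PlantedSite]] = {}
    for ps in planted:
        planted_by_gene.setdefault(ps.gene_id, []).append(ps)
    _write_maf(out / "alignment.maf", genes, genome_len, config, planted_by_gene, rng)
    write_seed_table(families, out / "seeds.tsv")
    clade_of = {
        sp: clade for clade in CLADE_ORDER for sp in config.species_of_clade[clade]
    }
    write_clade_table(
        CladeTable(clade_of=clade_of, reference=config.reference_species),
        out / "clades.tsv",
    )

    lnc_ids = [g.gene_id for g in genes if g.kind == "lnc"]
    coding_ids = [g.gene_id for g in genes if g.kind == "coding"]
    cyto = {
        gid for gid in lnc_ids if rng.random() < config.cyto_bias_fraction
    }
    cyto |= set(coding_ids)  # mRNAs are predominantly cytoplasmic
    truth = GroundTruth(planted_sites=planted, true_cytoplasmic_genes=cyto)
    counts = generate_counts([g.gene_id for g in genes], truth, config, rng)
    counts.to_csv(out / "counts.tsv", sep="\t")
    return truth
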