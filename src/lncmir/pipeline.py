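"""End-to-end orchestration: annotate -> scan -> conserve -> null -> localize
-> enrich, with a machine-readable results bundle.

Every stage is a pure function of its inputs plus the run RNG seed; re-running
a configuration reproduces the bundle byte-for-byte (modulo the timestamp in
the metadata, which is omitted for that reason).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    DEFAULT_MIN_SEPARATION,
    parse_gtf,
    read_symbol_list,
    select_intergenic,
    select_lncrna_genes,
    write_exclusion_report,
    write_gene_bed,
)
from .background import (
    DEFAULT_N_SETS,
    count_sites_by_stratum,
    fit_dinuc_model,
    sample_seed_sets,
    write_seed_sets,
)
from .conservation import (
    CLADE_ORDER,
    ConservationConfig,
    load_maf,
    read_clade_table,
    stratify_sites,
)
from .enrichment import (
    compute_enrichment,
    empirical_significance,
    site_report,
    write_enrichment_table,
)
from .localization import (
    DEFAULT_MIN_TOTAL_READS,
    classify_localization,
    intersect_subsets,
    read_counts_tsv,
    write_localization_calls,
)
from .seeds import SITE_TYPES, SeedFamily, TargetSite, read_seed_table

log = logging.getLogger(__name__)

#: transcript subsets of the stringency grid
SUBSETS = ("lnc_all", "lnc_intergenic", "lnc_cyto_intergenic", "coding_utr3", "coding_cds")


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class RunConfig:
    gtf: str
    fasta: str
    maf: str
    clades: str
    seeds: str
    counts: str | None = None
    coding_symbols: str | None = None
    out_dir: str = "lncmir_results"
    rng_seed: int = 17
    n_random_sets: int = DEFAULT_N_SETS
    min_separation: int = DEFAULT_MIN_SEPARATION
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS
    min_fraction: float = 0.5
    require_reference: bool = True
    tiers: tuple[str, ...] = CLADE_ORDER
    site_types: tuple[str, ...] = SITE_TYPES
    subsets: tuple[str, ...] = SUBSETS
    family_classes: tuple[str, ...] = ("conserved", "nonconserved")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("tiers", "site_types", "subsets", "family_classes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(cfg: RunConfig) -> ValidationReport:
    """Cross-consistency checks on the input bundle; findings are reported,
    not raised."""
    report = ValidationReport()
    paths = {"gtf": cfg.gtf, "fasta": cfg.fasta, "maf": cfg.maf, "clades": cfg.clades, "seeds": cfg.seeds}
    if cfg.counts:
        paths["counts"] = cfg.counts
    missing = {name for name, p in paths.items() if not Path(p).exists()}
    for name in sorted(missing):
        report.fatal.append(f"{name}: file not found: {paths[name]}")
    if missing:
        return report

    from pyfaidx import Fasta

    contigs = set(Fasta(cfg.fasta).keys())
    gtf_contigs = set()
    with open(cfg.gtf) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gtf_contigs.add(line.split("\t", 1)[0])
    for c in sorted(gtf_contigs - contigs):
        report.fatal.append(f"gtf: contig {c!r} absent from FASTA")

    try:
        clades = read_clade_table(cfg.clades)
    except ValueError as exc:
        report.fatal.append(f"clades: {exc}")
        clades = None
    maf_species = set()
    with open(cfg.maf) as fh:
        for line in fh:
            if line.startswith("s "):
                maf_species.add(line.split()[1].split(".", 1)[0])
    if clades is not None:
        for sp in sorted(maf_species - clades.species):
            report.fatal.append(f"maf: species {sp!r} absent from clade table")

    try:
        read_seed_table(cfg.seeds)
    except ValueError as exc:
        report.fatal.append(f"seeds: {exc}")
    if not report.fatal and not maf_species:
        report.warnings.append("maf: no alignment blocks found")
    return report


def _subset_filter(
    subset: str,
    lnc_ids: set[str],
    intergenic_ids: set[str],
    cyto_intergenic_ids: set[str],
):
    if subset == "lnc_all":
        return lambda s: s.region == "LNC" and s.gene_id in lnc_ids
    if subset == "lnc_intergenic":
        return lambda s: s.region == "LNC" and s.gene_id in intergenic_ids
    if subset == "lnc_cyto_intergenic":
        return lambda s: s.region == "LNC" and s.gene_id in cyto_intergenic_ids
    if subset == "coding_utr3":
        return lambda s: s.region == "UTR3"
    if subset == "coding_cds":
        return lambda s: s.region == "CDS"
    raise PipelineError(f"enrichment: unknown subset {subset!r}")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the results bundle directory.

    The bundle holds the lncRNA set report, localization calls, per-class
    enrichment tables over the whole stringency grid, a site report for the
    most stringent cytoplasmic stratum, the sampled null seed sets, and run
    metadata.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(cfg)
    if not report.ok:
        stage = report.fatal[0].split(":", 1)[0]
        alias = {"maf": "conservation", "clades": "conservation"}.get(stage, stage)
        raise PipelineError(f"{alias}: " + "; ".join(report.fatal))

    log.info("stage annotation: parsing %s", cfg.gtf)
    genes = parse_gtf(cfg.gtf, cfg.fasta)
    symbols = read_symbol_list(cfg.coding_symbols) if cfg.coding_symbols else set()
    lnc_genes, lnc_report = select_lncrna_genes(genes, symbols)
    intergenic = select_intergenic(lnc_genes, genes, cfg.min_separation)
    lnc_report.n_intergenic_genes = len(intergenic)
    lnc_report.n_intergenic_transcripts = sum(len(g.transcripts) for g in intergenic)
    log.info(
        "stage annotation: %d genes in, %d lncRNA, %d intergenic",
        lnc_report.n_genes_in,
        lnc_report.n_lncrna_genes,
        lnc_report.n_intergenic_genes,
    )
    write_exclusion_report(lnc_report, out / "lncrna_exclusions.tsv")
    write_gene_bed(intergenic, out / "intergenic_lncrna.bed")

    cyto_intergenic = intergenic
    calls = []
    if cfg.counts:
        log.info("stage localization: %s", cfg.counts)
        try:
            counts = read_counts_tsv(cfg.counts)
            calls = classify_localization(counts, cfg.min_total_reads)
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"localization: {exc}") from exc
        write_localization_calls(calls, out / "localization_calls.tsv")
        cyto_intergenic = intersect_subsets(intergenic, calls)
        log.info(
            "stage localization: %d/%d intergenic lncRNAs cytoplasmic",
            len(cyto_intergenic),
            len(intergenic),
        )

    log.info("stage conservation: indexing %s", cfg.maf)
    try:
        clades = read_clade_table(cfg.clades)
        index = load_maf(cfg.maf, clades, fasta=cfg.fasta)
    except ValueError as exc:
        raise PipelineError(f"conservation: {exc}") from exc
    cons_cfg = ConservationConfig(
        min_fraction=cfg.min_fraction, require_reference=cfg.require_reference
    )

    families = read_seed_table(cfg.seeds)
    transcripts = [t for g in genes for t in g.transcripts]
    lnc_ids = {g.gene_id for g in lnc_genes}
    intergenic_ids = {g.gene_id for g in intergenic}
    cyto_ids = {g.gene_id for g in cyto_intergenic}
    filters = {
        sub: _subset_filter(sub, lnc_ids, intergenic_ids, cyto_ids)
        for sub in cfg.subsets
    }

    conserved = [f for f in families if f.conservation_class == "conserved"]
    if not conserved:
        raise PipelineError("background: no conserved families in seed table")
    model = fit_dinuc_model([f.seed for f in conserved])
    seed_sets = sample_seed_sets(
        model,
        set_size=len(conserved),
        real_seeds={f.seed for f in conserved},
        rng_seed=cfg.rng_seed,
        n_sets=cfg.n_random_sets,
    )
    write_seed_sets(seed_sets, out / "random_seed_sets.tsv")

    def stratified(site_list: list[TargetSite], subset: str) -> dict:
        return stratify_sites(
            [s for s in site_list if filters[subset](s)], cfg.tiers, cfg.site_types
        )

    results_by_class = {}
    cyto_sites_8mer_mammal: list[TargetSite] = []
    for fam_class in cfg.family_classes:
        class_families = [f for f in families if f.conservation_class == fam_class]
        if not class_families:
            continue
        log.info(
            "stage scan: %d %s families x %d transcripts",
            len(class_families),
            fam_class,
            len(transcripts),
        )
        _, observed_sites = count_sites_by_stratum(
            class_families, transcripts, index, clades, cons_cfg,
            cfg.tiers, cfg.site_types,
        )
        observed = {sub: stratified(observed_sites, sub) for sub in cfg.subsets}
        if fam_class == "conserved":
            cyto_sites_8mer_mammal = [
                s
                for s in observed_sites
                if filters.get("lnc_cyto_intergenic", lambda s: False)(s)
                and s.site_type == "8mer"
                and s.conservation is not None
                and s.conservation.tier in ("mammal", "vertebrate")
            ]
        log.info("stage null: %d random sets", len(seed_sets))
        per_set_sites = {}
        for seed_set in seed_sets:
            null_families = [
                SeedFamily(f"set{seed_set.set_index}_seed{i:03d}", s, "random")
                for i, s in enumerate(seed_set.seeds, start=1)
            ]
            _, null_sites = count_sites_by_stratum(
                null_families, transcripts, index, clades, cons_cfg,
                cfg.tiers, cfg.site_types,
            )
            per_set_sites[seed_set.set_index] = null_sites
        results = []
        for sub in cfg.subsets:
            null_counts = {
                k: stratified(v, sub) for k, v in per_set_sites.items()
            }
            for tier in cfg.tiers:
                for st in cfg.site_types:
                    obs = observed[sub][(tier, st)]
                    rand = [null_counts[k][(tier, st)] for k in sorted(null_counts)]
                    res = compute_enrichment(obs, rand, stratum=(sub, fam_class, tier, st))
                    sub_sites = [
                        s for s in observed_sites
                        if filters[sub](s) and s.site_type == st
                        and s.conservation is not None
                        and s.conservation.tier != "none"
                    ]
                    res.n_target_genes = len({s.gene_id for s in sub_sites})
                    res.n_families_with_sites = len({s.family_name for s in sub_sites})
                    results.append(res)
        write_enrichment_table(results, out / f"enrichment_{fam_class}.tsv")
        results_by_class[fam_class] = results

    gene_symbols = {g.gene_id: g.symbol for g in genes}
    table, summary = site_report(cyto_sites_8mer_mammal, gene_symbols)
    table.to_csv(out / "site_report.tsv", sep="\t", index=False)

    metadata = {
        "version": __version__,
        "rng_seed": cfg.rng_seed,
        "n_random_sets": cfg.n_random_sets,
        "thresholds": {
            "min_isoform_length": 200,
            "min_separation": cfg.min_separation,
            "min_total_reads": cfg.min_total_reads,
            "clade_min_fraction": cfg.min_fraction,
        },
        "lncrna_report": asdict(lnc_report),
        "site_report_summary": {
            "n_sites": summary[0],
            "n_genes": summary[1],
            "n_families": summary[2],
        },
        "headline": {
            "|".join(map(str, r.stratum)): {
                "observed": r.observed,
                "expected": r.expected,
                "ratio": None if r.ratio != r.ratio else round(r.ratio, 4),
                "empirical_p": r.empirical_p,
                "fdr": None if r.fdr != r.fdr else round(r.fdr, 4),
                "label": empirical_significance(r),
            }
            for results in results_by_class.values()
            for r in results
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    log.info("results bundle written to %s", out)
    return out
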