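"""Observed-to-expected enrichment statistics with an empirical null.

Expected counts are the arithmetic mean over the random seed sets; the
enrichment ratio is observed/expected; the empirical P-value is the fraction
of random sets whose count reaches the observed count (ties count as
exceeding, the conservative choice); the implied false discovery rate is
expected/observed capped at 1 — e.g. a 1.8-fold enrichment corresponds to an
FDR of 56%. With the standard 20 random sets, significance labels follow the
quantized rule: at least 19/20 sets below the observed count for P <= 0.05,
18/20 for P = 0.10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seeds import TargetSite, dedupe_gene_level


@dataclass
class EnrichmentResult:
    """Enrichment of observed sites over the random-seed expectation for one
    stringency stratum.

    ``ratio`` is observed over the mean per-set count (primary statistic);
    ``ratio_mean_of_ratios`` averages the per-set ratios instead and is kept
    as metadata. ``unreliable`` flags strata whose expected count is below 1,
    where the ratio is not meaningful ("n/a" in reports).
    """

    observed: int
    random_counts: list[int]
    expected: float = 0.0
    ratio: float = math.nan
    ratio_mean_of_ratios: float = math.nan
    n_exceeding: int = 0
    empirical_p: float = math.nan
    fdr: float = 1.0
    unreliable: bool = False
    stratum: tuple = ()
    n_target_genes: int = 0
    n_families_with_sites: int = 0
    metadata: dict = field(default_factory=dict)


def compute_enrichment(
    observed: int,
    random_counts: list[int],
    stratum: tuple = (),
) -> EnrichmentResult:
    """Observed vs the random-set null for one stratum.

    Degenerate cases follow the reporting conventions: observed 0 gives ratio
    0, P 1 and FDR 1; expected 0 with observed > 0 gives an undefined ratio
    flagged unreliable ("n/a, observed counts too low").
    """
    if observed < 0 or any(c < 0 for c in random_counts):
        raise ValueError("counts must be non-negative")
    if not random_counts:
        raise ValueError("at least one random set required")
    res = EnrichmentResult(
        observed=observed, random_counts=list(random_counts), stratum=stratum
    )
    res.expected = sum(random_counts) / len(random_counts)
    res.n_exceeding = sum(1 for c in random_counts if c >= observed)
    res.empirical_p = res.n_exceeding / len(random_counts)
    if observed == 0:
        res.ratio = 0.0
        res.fdr = 1.0
    elif res.expected > 0:
        res.ratio = observed / res.expected
        res.fdr = min(1.0, res.expected / observed)
    else:
        res.ratio = math.nan  # n/a: no random set produced any site
        res.fdr = math.nan
        res.unreliable = True
    per_set = [observed / c for c in random_counts if c > 0]
    if per_set:
        res.ratio_mean_of_ratios = sum(per_set) / len(per_set)
    if res.expected < 1:
        res.unreliable = True
    return res


def empirical_significance(result: EnrichmentResult) -> str:
    """Quantized significance label under the 20-set rule.

    "P<=0.05" needs >= 19/20 random sets below the observed count
    (n_exceeding <= 1); "P=0.10" corresponds to exactly 18/20 (n_exceeding 2);
    anything weaker is "ns". With a set count other than 20 the quantized
    labels do not apply and the generic empirical P is reported instead.
    """
    n = len(result.random_counts)
    if n != 20:
        return f"P={result.empirical_p:.3g}"
    if result.n_exceeding <= 1:
        return "P<=0.05"
    if result.n_exceeding == 2:
        return "P=0.10"
    return "ns"


def site_report(
    sites: list[TargetSite],
    symbols: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """Table of gene-level sites plus a (sites, genes, families) summary.

    One row per gene-level site — isoform-shared sites collapse to one row —
    with 1-based genome positions in the output, sorted by gene id then
    position.
    """
    symbols = symbols or {}
    rows = []
    for s in dedupe_gene_level(sites):
        rows.append(
            {
                "gene_id": s.gene_id,
                "symbol": symbols.get(s.gene_id, s.gene_id),
                "family": s.family_name,
                "site_type": s.site_type,
                "chrom": s.genome_chrom,
                "position": s.genome_pos + 1,
                "tier": s.conservation.tier if s.conservation else "none",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "family",
            "site_type",
            "chrom",
            "position",
            "tier",
        ],
    )
    if len(df):
        df = df.sort_values(["gene_id", "position"]).reset_index(drop=True)
    summary = (
        len(df),
        df["gene_id"].nunique() if len(df) else 0,
        df["family"].nunique() if len(df) else 0,
    )
    return df, summary


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        label = empirical_significance(r)
        rows.append(
            {
                "stratum": "|".join(str(x) for x in r.stratum),
                "observed": r.observed,
                "expected": round(r.expected, 4),
                "ratio": "n/a" if math.isnan(r.ratio) else round(r.ratio, 4),
                "ratio_mean_of_ratios": (
                    "n/a"
                    if math.isnan(r.ratio_mean_of_ratios)
                    else round(r.ratio_mean_of_ratios, 4)
                ),
                "empirical_p": round(r.empirical_p, 4),
                "fdr": "n/a" if math.isnan(r.fdr) else round(r.fdr, 4),
                "label": label,
                "unreliable": r.unreliable,
                "n_target_genes": r.n_target_genes,
                "n_families_with_sites": r.n_families_with_sites,
            }
        )
    return pd.DataFrame(rows)


def write_enrichment_table(results: list[EnrichmentResult], path: str | Path) -> None:
    enrichment_table(results).to_csv(path, sep="\t", index=False)
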