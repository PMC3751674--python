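"""Cytoplasmic/nuclear localization calls from fractionated RNA-seq counts.

Each library is scaled to counts per million, cytoplasmic and nuclear CPM are
pooled across cell lines, and a gene is called cytoplasmic when the pooled
cytoplasm/nucleus ratio exceeds 1 and the gene has at least 20 raw mapped
reads summed over all libraries (the depth filter guards against unstable
ratios at low abundance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import GeneModel

FRACTIONS = ("cytoplasm", "nucleus")

#: minimum raw reads summed over all libraries for a reliable ratio
DEFAULT_MIN_TOTAL_READS = 20

#: pseudocount added to pooled CPM in numerator and denominator
CPM_PSEUDOCOUNT = 0.5


@dataclass
class FractionCounts:
    """Gene x library count matrix with ``<cellline>_<fraction>`` columns.

    ``library_sizes`` defaults to column sums (total mapped reads per
    library). Every cell line must contribute both fractions.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for lib in self.counts.columns:
            cell, _, fraction = lib.rpartition("_")
            if fraction not in FRACTIONS or not cell:
                raise ValueError(
                    f"library {lib!r} not named <cellline>_<fraction>"
                )
        for cell in self.cell_lines:
            for fraction in FRACTIONS:
                if f"{cell}_{fraction}" not in self.counts.columns:
                    raise ValueError(f"cell line {cell!r} missing {fraction} fraction")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise ValueError(f"zero library size for {bad}")

    @property
    def cell_lines(self) -> list[str]:
        return sorted({lib.rpartition("_")[0] for lib in self.counts.columns})


@dataclass
class LocalizationCall:
    gene_id: str
    total_reads: int
    normalized_ratio: float
    passed_depth_filter: bool
    is_cytoplasmic: bool


def read_counts_tsv(path: str | Path) -> FractionCounts:
    """Counts TSV: gene_id column then ``<cellline>_<fraction>`` columns;
    library sizes are taken as column sums."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return FractionCounts(counts=df)


def classify_localization(
    counts: FractionCounts,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
    per_line_median: bool = False,
) -> list[LocalizationCall]:
    """Cytoplasmic calls per gene.

    Primary normalization pools CPM across cell lines before the ratio (robust
    to zeros in individual lines); ``per_line_median`` instead takes the
    median of per-cell-line CPM ratios.
    """
    df = counts.counts
    cpm = df / counts.library_sizes * 1e6
    cyt_cols = [c for c in df.columns if c.endswith("_cytoplasm")]
    nuc_cols = [c for c in df.columns if c.endswith("_nucleus")]
    if per_line_median:
        ratios = pd.concat(
            {
                cell: (cpm[f"{cell}_cytoplasm"] + CPM_PSEUDOCOUNT)
                / (cpm[f"{cell}_nucleus"] + CPM_PSEUDOCOUNT)
                for cell in counts.cell_lines
            },
            axis=1,
        ).median(axis=1)
    else:
        ratios = (cpm[cyt_cols].sum(axis=1) + CPM_PSEUDOCOUNT) / (
            cpm[nuc_cols].sum(axis=1) + CPM_PSEUDOCOUNT
        )
    totals = df.sum(axis=1)
    calls = []
    for gene_id in df.index:
        total = int(totals[gene_id])
        ratio = float(ratios[gene_id])
        passed = total >= min_total_reads
        calls.append(
            LocalizationCall(
                gene_id=gene_id,
                total_reads=total,
                normalized_ratio=ratio,
                passed_depth_filter=passed,
                is_cytoplasmic=passed and ratio > 1,
            )
        )
    return calls


def intersect_subsets(
    lnc_genes: list[GeneModel], calls: list[LocalizationCall]
) -> list[GeneModel]:
    """Intergenic lncRNA genes called cytoplasmic, sorted by gene_id."""
    cyto = {c.gene_id for c in calls if c.is_cytoplasmic}
    return sorted(
        (g for g in lnc_genes if g.gene_id in cyto), key=lambda g: g.gene_id
    )


def write_localization_calls(calls: list[LocalizationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttotal_reads\tnormalized_ratio\tpassed_depth_filter\tis_cytoplasmic\n"
        )
        for c in sorted(calls, key=lambda x: x.gene_id):
            fh.write(
                f"{c.gene_id}\t{c.total_reads}\t{c.normalized_ratio:.4f}"
                f"\t{c.passed_depth_filter}\t{c.is_cytoplasmic}\n"
            )
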