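"""GTF/FASTA parsing and lncRNA set construction.

Reproduces the standard long-non-coding gene selection: keep genes whose every
isoform has a long-non-coding biotype, drop pseudogenes, drop genes with any
isoform shorter than 200 nt, drop genes whose symbol matches a user-supplied
coding-gene symbol list, and optionally restrict to intergenic genes separated
by at least 10 kb from any other annotated gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from pyfaidx import Fasta

from .models import GeneModel, TranscriptModel, gene_gap, reverse_complement

log = logging.getLogger(__name__)

#: transcript biotypes admitted into the long-non-coding set
LNC_BIOTYPES = frozenset({"antisense", "lincRNA", "non_coding", "processed_transcript"})

#: minimum spliced isoform length for a gene to stay in the lncRNA set (nt)
MIN_ISOFORM_LENGTH = 200

#: default minimum genomic separation for the intergenic subset (nt)
DEFAULT_MIN_SEPARATION = 10_000


@dataclass
class LncrnaSetReport:
    """Bookkeeping for the lncRNA set construction.

    Gene and transcript counts are recorded separately and explicitly at every
    stage so the two are never confused in downstream summaries.
    """

    n_genes_in: int = 0
    n_lncrna_genes: int = 0
    n_lncrna_transcripts: int = 0
    n_intergenic_genes: int = 0
    n_intergenic_transcripts: int = 0
    excluded: dict[str, str] = field(default_factory=dict)


def _region_label(feature_type: str) -> str | None:
    ft = feature_type.lower()
    if ft == "cds":
        return "CDS"
    if ft in ("five_prime_utr", "5utr", "utr5"):
        return "UTR5"
    if ft in ("three_prime_utr", "3utr", "utr3"):
        return "UTR3"
    return None


def _genomic_to_transcript_intervals(
    t: TranscriptModel, gstart: int, gend: int
) -> list[tuple[int, int]]:
    """Project a genomic interval onto transcript coordinates via the exons."""
    pieces = []
    offset = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for start, end in exons:
        lo, hi = max(start, gstart), min(end, gend)
        if lo < hi:
            if t.strand == "+":
                pieces.append((offset + (lo - start), offset + (hi - start)))
            else:
                pieces.append((offset + (end - hi), offset + (end - lo)))
        offset += end - start
    return sorted(pieces)


def parse_gtf(gtf: str | Path, fasta: str | Path) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF plus genome FASTA into gene models.

    Spliced sequences are extracted strand-aware (minus-strand transcripts
    reverse-complemented). GTF 1-based inclusive coordinates are converted to
    0-based half-open. Raises ``ValueError`` when an exon lies outside its
    FASTA contig or a required attribute is missing.
    """
    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        try:
            gene_id = g.attributes["gene_id"][0]
        except KeyError:
            raise ValueError(f"gene feature at {g.seqid}:{g.start} lacks gene_id")
        symbol = g.attributes.get("gene_name", [gene_id])[0]
        gene = GeneModel(
            gene_id=gene_id,
            symbol=symbol,
            chrom=g.seqid,
            strand=g.strand,
            gene_biotype=g.attributes.get("gene_type", [""])[0],
        )
        for tr in db.children(g, featuretype="transcript"):
            try:
                tid = tr.attributes["transcript_id"][0]
            except KeyError:
                raise ValueError(f"transcript under {gene_id} lacks transcript_id")
            biotype = tr.attributes.get(
                "transcript_type", tr.attributes.get("gene_type", [""])
            )[0]
            exons = [
                (e.start - 1, e.end) for e in db.children(tr, featuretype="exon")
            ]
            if not exons:
                raise ValueError(f"transcript {tid} has no exons")
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=g.seqid,
                strand=g.strand,
                exons=exons,
                biotype=biotype,
            )
            if g.seqid not in genome:
                raise ValueError(f"contig {g.seqid} (transcript {tid}) not in FASTA")
            contig = genome[g.seqid]
            contig_len = len(contig)
            parts = []
            for start, end in model.exons:
                if start < 0 or end > contig_len:
                    raise ValueError(
                        f"exon {g.seqid}:{start}-{end} of {tid} outside contig"
                    )
                parts.append(contig[start:end])
            seq = "".join(parts)
            model.spliced_seq = seq if g.strand == "+" else reverse_complement(seq)
            for ft in ("CDS", "five_prime_utr", "three_prime_utr"):
                for feat in db.children(tr, featuretype=ft):
                    label = _region_label(feat.featuretype)
                    ivs = _genomic_to_transcript_intervals(
                        model, feat.start - 1, feat.end
                    )
                    model.regions.setdefault(label, []).extend(ivs)
            for label in model.regions:
                model.regions[label] = sorted(model.regions[label])
            gene.transcripts.append(model)
        if gene.transcripts:
            genes.append(gene)
    genes.sort(key=lambda g: g.gene_id)
    return genes


def _exclusion_reason(gene: GeneModel, coding_symbols: set[str]) -> str | None:
    if any("pseudogene" in bt for bt in gene.biotypes):
        return "pseudogene biotype"
    if not gene.biotypes <= LNC_BIOTYPES:
        return "non-lnc biotype"
    if any(t.spliced_length < MIN_ISOFORM_LENGTH for t in gene.transcripts):
        return f"isoform <{MIN_ISOFORM_LENGTH} nt"
    if gene.symbol.lower() in coding_symbols:
        return "coding symbol"
    return None


def select_lncrna_genes(
    genes: list[GeneModel], coding_symbols: set[str] | None = None
) -> tuple[list[GeneModel], LncrnaSetReport]:
    """Build the long-non-coding gene set.

    A gene is kept iff every transcript biotype is one of ``LNC_BIOTYPES``, no
    biotype string contains "pseudogene", every isoform is >= 200 nt spliced,
    and its symbol (case-insensitive) is not in ``coding_symbols``. One reason
    is recorded per excluded gene, in that precedence order.
    """
    symbols = {s.lower() for s in (coding_symbols or set())}
    report = LncrnaSetReport(n_genes_in=len(genes))
    kept = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        reason = _exclusion_reason(gene, symbols)
        if reason is None:
            kept.append(gene)
        else:
            report.excluded[gene.gene_id] = reason
    report.n_lncrna_genes = len(kept)
    report.n_lncrna_transcripts = sum(len(g.transcripts) for g in kept)
    log.info(
        "lncRNA set: %d/%d genes kept (%d transcripts)",
        report.n_lncrna_genes,
        report.n_genes_in,
        report.n_lncrna_transcripts,
    )
    return kept, report


def select_intergenic(
    lnc_genes: list[GeneModel],
    all_genes: list[GeneModel],
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[GeneModel]:
    """Keep lncRNA genes separated by >= ``min_separation`` nt from every other
    annotated gene on the same chromosome.

    Strand is ignored. Overlapping genes are never intergenic, regardless of
    ``min_separation``; abutting but non-overlapping genes have gap 0.
    """

    def overlaps(a: GeneModel, b: GeneModel) -> bool:
        (a0, a1), (b0, b1) = a.span, b.span
        return a0 < b1 and b0 < a1

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept = []
    for g in sorted(lnc_genes, key=lambda x: x.gene_id):
        neighbours = by_chrom.get(g.chrom, [])
        if all(
            h.gene_id == g.gene_id
            or (not overlaps(g, h) and gene_gap(g, h) >= min_separation)
            for h in neighbours
        ):
            kept.append(g)
    return kept


def subset_by_score(
    genes: list[GeneModel], scores: dict[str, float], top_n: int
) -> list[GeneModel]:
    """The ``top_n`` genes by descending score, ties broken by gene_id.

    Genes without a score are skipped with a warning. Mirrors taking e.g. the
    500 most promoter-conserved intergenic lncRNAs as an analysis subset.
    """
    scored = []
    for g in genes:
        if g.gene_id not in scores:
            warnings.warn(f"gene {g.gene_id} has no score; skipped", stacklevel=2)
            continue
        scored.append(g)
    scored.sort(key=lambda g: (-scores[g.gene_id], g.gene_id))
    return scored[:top_n]


def read_symbol_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    """BED6 of gene spans (score column 0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda x: x.gene_id):
            start, end = g.span
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def write_exclusion_report(report: LncrnaSetReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for gid in sorted(report.excluded):
            fh.write(f"{gid}\t{report.excluded[gid]}\n")
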