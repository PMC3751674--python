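from pathlib import Path

import pytest

from lncmir.models import GeneModel, TranscriptModel
from lncmir.seeds import SeedFamily


def write_fasta(path: Path, contigs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_gtf(path: Path, rows: list[str]) -> Path:
    path.write_text("\n".join(rows) + "\n")
    return path


def gtf_row(
    chrom: str,
    feature: str,
    start1: int,
    end1: int,
    strand: str,
    gene_id: str,
    transcript_id: str | None = None,
    gene_type: str = "lincRNA",
    gene_name: str | None = None,
) -> str:
    attrs = [f'gene_id "{gene_id}"']
    if transcript_id:
        attrs.append(f'transcript_id "{transcript_id}"')
    attrs.append(f'gene_type "{gene_type}"')
    if transcript_id:
        attrs.append(f'transcript_type "{gene_type}"')
    attrs.append(f'gene_name "{gene_name or gene_id}"')
    return "\t".join(
        [chrom, "test", feature, str(start1), str(end1), ".", strand, ".", "; ".join(attrs) + ";"]
    )


def make_transcript(
    seq: str,
    transcript_id: str = "T1",
    gene_id: str = "G1",
    chrom: str = "chr1",
    strand: str = "+",
    start: int = 0,
    regions: dict | None = None,
) -> TranscriptModel:
    """Single-exon transcript whose spliced (sense) sequence is ``seq``."""
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=[(start, start + len(seq))],
        spliced_seq=seq,
        biotype="lincRNA",
        regions=regions or {},
    )


def make_gene(
    gene_id: str,
    span: tuple[int, int],
    chrom: str = "chr1",
    strand: str = "+",
    biotype: str = "lincRNA",
    symbol: str | None = None,
    isoform_lengths: tuple[int, ...] | None = None,
) -> GeneModel:
    """Gene with one transcript per requested isoform length (dummy seq)."""
    start, end = span
    lengths = isoform_lengths or (end - start,)
    transcripts = [
        TranscriptModel(
            transcript_id=f"{gene_id}.t{i}",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=[(start, start + length)],
            spliced_seq="A" * length,
            biotype=biotype,
        )
        for i, length in enumerate(lengths, 1)
    ]
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=transcripts,
        gene_biotype=biotype,
    )


@pytest.fixture
def let7() -> SeedFamily:
    return SeedFamily("let-7", "GAGGUAG", "conserved")


@pytest.fixture
def maf_bundle(tmp_path):
    """Hand-written MAF + FASTA + clade table covering chr1:100-120.

    Reference ``prim01`` plus one extra primate, five placental mammals and
    seven non-mammal vertebrates; the reference row spells out
    GGCTACCTCAGGTTTTTTTT (a let-7 8mer at genomic 102-110).
    """
    ref_seq = "GGCTACCTCAGGTTTTTTTT"
    genome = "A" * 100 + ref_seq + "C" * 80
    fasta = write_fasta(tmp_path / "genome.fa", {"chr1": genome})
    species = {
        "prim01": "primate",
        "prim02": "primate",
        **{f"mamm{i:02d}": "mammal" for i in range(1, 6)},
        **{f"vert{i:02d}": "vertebrate" for i in range(1, 8)},
    }
    clades = tmp_path / "clades.tsv"
    clades.write_text(
        "species\tclade\n" + "".join(f"{s}\t{c}\n" for s, c in species.items())
    )
    intact = ref_seq
    broken = "GGCAACCACAGGTTTTTTTT"  # 8mer window disrupted at 2 positions
    rows = {
        "prim01": intact,
        "prim02": intact,
        "mamm01": intact,
        "mamm02": intact,
        "mamm03": intact,
        "mamm04": intact,
        "mamm05": broken,  # 4/5 mammal-only species intact
        **{f"vert{i:02d}": broken for i in range(1, 8)},
    }
    lines = ["##maf version=1", "", "a score=0"]
    for sp, seq in rows.items():
        lines.append(f"s {sp}.chr1 100 {len(seq)} + {len(genome)} {seq}")
    lines.append("")
    maf = tmp_path / "alignment.maf"
    maf.write_text("\n".join(lines))
    return {"fasta": fasta, "maf": maf, "clades": clades, "genome": genome}
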