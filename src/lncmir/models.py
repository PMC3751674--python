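"""Gene and transcript models with strand-aware coordinate mapping.

All genomic coordinates are 0-based half-open internally; GTF input/output is
converted at the boundary (1-based inclusive). Spliced transcript sequences are
stored on the sense strand (minus-strand transcripts are reverse-complemented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One splice isoform: exon structure plus the spliced sense-strand sequence.

    ``exons`` are genomic intervals (start, end), 0-based half-open, sorted in
    ascending genomic order regardless of strand. ``regions`` maps region labels
    (``UTR5``/``CDS``/``UTR3``) to lists of transcript-coordinate intervals; it
    is empty for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    spliced_seq: str = ""
    biotype: str = ""
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def transcript_to_genome(self, pos: int) -> int:
        """Genomic coordinate of the base at transcript position ``pos``."""
        if not 0 <= pos < self.spliced_length:
            raise IndexError(
                f"position {pos} outside transcript {self.transcript_id}"
            )
        if self.strand == "+":
            for start, end in self.exons:
                if pos < end - start:
                    return start + pos
                pos -= end - start
        else:
            for start, end in reversed(self.exons):
                if pos < end - start:
                    return end - 1 - pos
                pos -= end - start
        raise AssertionError("unreachable")

    def genome_positions(self, pos: int, length: int) -> list[int]:
        """Genomic coordinates of transcript bases pos..pos+length-1, in
        transcript (5'->3') order."""
        return [self.transcript_to_genome(p) for p in range(pos, pos + length)]

    def genome_intervals(self, pos: int, length: int) -> list[tuple[int, int]]:
        """Contiguous genomic intervals covering the transcript slice, in
        ascending genomic order."""
        positions = sorted(self.genome_positions(pos, length))
        intervals: list[tuple[int, int]] = []
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
                continue
            intervals.append((run_start, prev + 1))
            run_start = prev = p
        intervals.append((run_start, prev + 1))
        return intervals


@dataclass
class GeneModel:
    """A gene: outermost span plus its transcripts and their biotypes."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    gene_biotype: str = ""

    @property
    def biotypes(self) -> set[str]:
        return {t.biotype for t in self.transcripts}

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


def gene_gap(a: GeneModel, b: GeneModel) -> int:
    """Genomic separation between two gene spans; 0 when they overlap.

    Strand is ignored; genes on different chromosomes are infinitely separated
    (returns a large sentinel handled by callers comparing against thresholds).
    """
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    a0, a1 = a.span
    b0, b1 = b.span
    if a1 <= b0:
        return b0 - a1
    if b1 <= a0:
        return a0 - b1
    return 0
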