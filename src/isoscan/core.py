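"""Core genomic value types and interval algebra.

All coordinates are 0-based half-open internally.  GTF I/O converts to and
from the 1-based closed convention at the boundary (see :mod:`isoscan.io`),
and SAM ``POS`` is converted from 1-based at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A stranded exon chain with CDS boundaries.

    ``exons`` are disjoint, sorted by start and share one sequence/strand.
    ``cds_start``/``cds_end`` are genomic offsets (half-open) of the coding
    span; for the gene structures this toolkit predicts the exons are pure
    CDS, but annotated inputs may carry UTR exon sequence outside the CDS.
    ``source_tag`` distinguishes reference ("KNOWN") from predicted
    ("ALTSCAN") and merged ("MIXTURE") annotations.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int
    source_tag: str = "KNOWN"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))
        seqs = {e.sequence_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqs) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons mix sequences/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            if b.start - a.end < 1:
                raise ValueError(f"{self.transcript_id}: zero-length intron")
        if not (self.cds_start < self.cds_end):
            raise ValueError(f"{self.transcript_id}: empty CDS")
        if not self._offset_in_exons(self.cds_start) or not self._offset_in_exons(
            self.cds_end - 1
        ):
            raise ValueError(f"{self.transcript_id}: CDS boundary outside exons")

    def _offset_in_exons(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)

    @property
    def sequence_id(self) -> str:
        return self.exons[0].sequence_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.sequence_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def cds_exons(self) -> tuple[GenomicInterval, ...]:
        """Exon pieces clipped to the coding span."""
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s < t:
                out.append(GenomicInterval(self.sequence_id, s, t, self.strand))
        return tuple(out)

    def cds_length(self) -> int:
        return sum(len(e) for e in self.cds_exons())

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic (start, end) gaps between consecutive exons."""
        ex = self.exons
        return tuple((a.end, b.start) for a, b in zip(ex, ex[1:]))

    def internal_junctions(self) -> tuple[tuple[str, int, int, str], ...]:
        """Splice junction keys between consecutive *CDS* exons.

        Key is (sequence_id, intron genomic start, intron genomic end,
        strand); on the + strand the intron start is the donor site and the
        intron end the acceptor site, reversed on the - strand.
        """
        ex = self.cds_exons()
        return tuple(
            (self.sequence_id, a.end, b.start, self.strand)
            for a, b in zip(ex, ex[1:])
        )

    def cds_key(self) -> tuple:
        """Exact CDS identity: sequence, strand and ordered CDS exon coords."""
        return (
            self.sequence_id,
            self.strand,
            tuple((e.start, e.end) for e in self.cds_exons()),
        )

    def is_multi_exon(self) -> bool:
        return len(self.cds_exons()) > 1


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped read placement on a mature (spliced) transcript."""

    read_id: str
    target_id: str
    target_start: int
    aligned_length: int
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        if self.target_start < 0:
            raise ValueError("target_start must be >= 0")


def merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    tree = IntervalTree.from_tuples((s, e) for s, e in intervals if s < e)
    tree.merge_overlaps()
    return sum(iv.end - iv.begin for iv in tree)


def overlap_fraction(
    query: Transcript, features: Sequence[GenomicInterval]
) -> float:
    """Fraction of the transcript's exonic bases covered by the feature union.

    Strand of the features is ignored (repeat annotations are unstranded for
    this purpose); features on other sequences contribute nothing.
    """
    exons = query.exons
    if not exons:  # unreachable through the constructor, guards raw use
        raise ValueError("transcript has no exons")
    tree = IntervalTree.from_tuples(
        (f.start, f.end)
        for f in features
        if f.sequence_id == query.sequence_id and f.start < f.end
    )
    tree.merge_overlaps()
    covered = 0
    for e in exons:
        for iv in tree.overlap(e.start, e.end):
            covered += min(iv.end, e.end) - max(iv.begin, e.start)
    total = sum(len(e) for e in exons)
    return covered / total
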