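"""Readers and writers for FASTA, GTF, BED6 and a minimal SAM subset.

GTF is read and written in the GENCODE dialect (``gene_id``/``transcript_id``
attributes, 1-based closed coordinates); SAM parsing consumes only ungapped
transcript-space alignments (reads mapped to spliced mature transcripts, so
junctions appear as contiguous matches).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentRecord, GenomicInterval, Transcript

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending record."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{sequence_id: uppercase sequence}``.

    Ambiguity codes are preserved (uppercased, not resolved).  Duplicate ids
    and empty records raise :class:`FormatError`.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read transcripts from a GTF file (1-based closed -> 0-based half-open).

    Exon features define the exon chain; CDS features, when present, define
    the coding span.  Transcripts without CDS features are treated as fully
    coding across their exon extent.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc

    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tags: dict[str, str] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if "transcript_id" not in feat.attributes:
            raise FormatError(
                f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start} "
                "lacks a transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if feat.featuretype == "exon":
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, start, end, feat.strand)
            )
            genes[tid] = gid
            src = feat.attributes.get("source_tag", [None])[0]
            if src:
                tags[tid] = src
        else:
            cds.setdefault(tid, []).append((start, end))

    out = []
    for tid in order:
        ivs = sorted(exons[tid])
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        else:
            cds_start, cds_end = ivs[0].start, ivs[-1].end
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=genes[tid],
                exons=tuple(ivs),
                cds_start=cds_start,
                cds_end=cds_end,
                source_tag=tags.get(tid, "KNOWN"),
            )
        )
    return out


def write_gtf(transcripts: Sequence[Transcript], path: str | Path, source: str = "isoscan") -> None:
    """Write transcripts as GTF (exon + CDS features, 1-based closed)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'source_tag "{t.source_tag}";'
            )
            for e in t.exons:
                fh.write(
                    f"{t.sequence_id}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            for c in t.cds_exons():
                fh.write(
                    f"{t.sequence_id}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED6


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED6 (or BED3, strand defaulting to '+') intervals."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\tregion{i}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# SAM (minimal subset: ungapped transcript-space alignments)


def read_sam_subset(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM file of ungapped alignments against mature transcripts.

    Unmapped records are skipped; records whose CIGAR is anything other than
    a single match run (M/=/X) are rejected with a logged count.  A mapped
    record naming a target absent from the header is a format error.
    """
    records: list[AlignmentRecord] = []
    rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        targets = set(sam.references)
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.reference_name not in targets:  # pragma: no cover - pysam pre-checks
                raise FormatError(
                    f"{path}: alignment target {aln.reference_name!r} not in header"
                )
            cig = aln.cigartuples or []
            if len(cig) != 1 or cig[0][0] not in (0, 7, 8):
                rejected += 1
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_id=aln.reference_name,
                    target_start=aln.reference_start,
                    aligned_length=cig[0][1],
                    mismatches=int(nm),
                )
            )
    if rejected:
        logger.info("read_sam_subset(%s): rejected %d gapped/clipped records", path, rejected)
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    target_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write ungapped alignments as a minimal text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in target_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        tid_index = {name: i for i, name in enumerate(target_lengths)}
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            a.flag = 0
            a.reference_id = tid_index[rec.target_id]
            a.reference_start = rec.target_start
            a.mapping_quality = 255
            a.cigarstring = f"{rec.aligned_length}M"
            a.query_sequence = "N" * rec.aligned_length
            a.set_tag("NM", rec.mismatches)
            sam.write(a)
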