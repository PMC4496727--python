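"""Deterministic generators for every input class the toolkit consumes.

The bundled gene model (:func:`fixture_spec`) defines the study conditions
for all simulation-based tests: a GENSCAN-like topology with information-rich
splice-site weight matrices (real donor/acceptor sites are sharply
constrained), codon-position-dependent coding composition, geometric intron
and intergenic lengths and histogram exon lengths on the scale of compact
vertebrate genes.  Read simulation places junction-spanning reads with
controllable per-side overhangs plus tiling reads for transcript-body
coverage, and emits a truth table of per-junction coverage so downstream
tallies can be verified in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AlignmentRecord, GenomicInterval, Transcript
from . import io as iso_io
from .ghmm import (
    ACCEPTOR_OFFSET,
    DONOR_OFFSET,
    EINIT,
    EINT,
    ESNGL,
    ETERM,
    INTRON,
    N,
    START_OFFSET,
    DurationModel,
    GhmmSpec,
    MarkovChain,
    PWM,
    sample_with_paths,
)
from .proteo import REFSEQ, VMC, PeptideHit
from .validate import ValidationConfig, build_mature

AA = "ACDEFGHIKLMNPQRSTVWY"


def _uniform_rows(n_rows: int, probs: Sequence[float]) -> np.ndarray:
    return np.tile(np.asarray(probs, dtype=float), (n_rows, 1))


def _pwm_rows(consensus: str, strength: float = 0.7) -> np.ndarray:
    """One row per consensus base; 'N' means uniform."""
    rows = []
    for c in consensus:
        if c == "N":
            rows.append([0.25, 0.25, 0.25, 0.25])
        else:
            row = [(1 - strength) / 3] * 4
            row["ACGT".index(c)] = strength
            rows.append(row)
    return np.array(rows)


def fixture_spec(order: int = 2) -> GhmmSpec:
    """The default generative gene model used by all fixtures."""
    n_ctx = 4**order
    noncoding = MarkovChain(order, _uniform_rows(n_ctx, [0.3, 0.2, 0.2, 0.3]))
    coding = [
        MarkovChain(order, _uniform_rows(n_ctx, [0.26, 0.20, 0.34, 0.20])),
        MarkovChain(order, _uniform_rows(n_ctx, [0.30, 0.25, 0.20, 0.25])),
        MarkovChain(order, _uniform_rows(n_ctx, [0.16, 0.30, 0.32, 0.22])),
    ]
    # windows follow the model geometry: donor = first 6 intron bases (GT
    # fixed), acceptor = last 13 intron bases (AG fixed), start = ATG triplet
    donor = PWM(DONOR_OFFSET, _pwm_rows("GTAAGT"), required={0: "G", 1: "T"})
    acceptor = PWM(
        ACCEPTOR_OFFSET,
        np.vstack(
            [
                _uniform_rows(9, [0.08, 0.38, 0.08, 0.46]),  # polypyrimidine tract
                _pwm_rows("NC"),
                _pwm_rows("AG", 0.97),
            ]
        ),
        required={11: "A", 12: "G"},
    )
    start = PWM(START_OFFSET, _pwm_rows("ATG", 0.97), required={0: "A", 1: "T", 2: "G"})
    uniform = lambda lo, hi: DurationModel(
        "hist", lo, probs=np.full(hi - lo + 1, 1.0 / (hi - lo + 1))
    )
    return GhmmSpec(
        transitions={
            N: {EINIT: 0.8, ESNGL: 0.2},
            EINIT: {INTRON: 1.0},
            EINT: {INTRON: 1.0},
            INTRON: {EINT: 0.4, ETERM: 0.6},
            ETERM: {N: 1.0},
            ESNGL: {N: 1.0},
        },
        durations={
            N: DurationModel("geom", 1, geom_p=1 / 150.0),
            INTRON: DurationModel("geom", 20, geom_p=1 / 61.0),
            EINIT: uniform(30, 120),
            EINT: uniform(30, 150),
            ETERM: uniform(30, 120),
            ESNGL: uniform(120, 300),
        },
        donor_pwm=donor,
        acceptor_pwm=acceptor,
        start_pwm=start,
        stop_probs={"TAA": 0.3, "TAG": 0.2, "TGA": 0.5},
        coding=coding,
        noncoding=noncoding,
        pseudocount=1.0,
    )


def reduced_spec(order: int = 0) -> GhmmSpec:
    """A small single-exon-only model for exhaustive-enumeration tests.

    Only the intergenic and single-exon states remain, exon lengths are
    short, and the content chains are order-0, so every legal segmentation
    of a <=30 nt sequence can be enumerated by brute force.
    """
    n_ctx = 4**order
    base = fixture_spec(order=2)
    return GhmmSpec(
        transitions={N: {ESNGL: 1.0}, ESNGL: {N: 1.0}},
        durations={
            N: DurationModel("geom", 1, geom_p=0.1),
            ESNGL: DurationModel("hist", 6, probs=np.full(25, 1 / 25.0)),
        },
        donor_pwm=base.donor_pwm,
        acceptor_pwm=base.acceptor_pwm,
        start_pwm=PWM(START_OFFSET, _pwm_rows("ATG", 0.97), required={0: "A", 1: "T", 2: "G"}),
        stop_probs={"TAA": 0.3, "TAG": 0.2, "TGA": 0.5},
        coding=[
            MarkovChain(order, _uniform_rows(n_ctx, [0.26, 0.20, 0.34, 0.20])),
            MarkovChain(order, _uniform_rows(n_ctx, [0.30, 0.25, 0.20, 0.25])),
            MarkovChain(order, _uniform_rows(n_ctx, [0.16, 0.30, 0.32, 0.22])),
        ],
        noncoding=MarkovChain(order, _uniform_rows(n_ctx, [0.3, 0.2, 0.2, 0.3])),
        pseudocount=1.0,
    )


def reduced_multiexon_spec() -> GhmmSpec:
    """Reduced model retaining introns, for enumeration on ~30 nt toys."""
    spec = reduced_spec(order=0)
    base = fixture_spec()
    return GhmmSpec(
        transitions={
            N: {ESNGL: 0.4, EINIT: 0.6},
            EINIT: {INTRON: 1.0},
            EINT: {INTRON: 1.0},
            INTRON: {EINT: 0.3, ETERM: 0.7},
            ETERM: {N: 1.0},
            ESNGL: {N: 1.0},
        },
        durations={
            N: DurationModel("geom", 1, geom_p=0.1),
            INTRON: DurationModel("geom", 20, geom_p=0.2),
            EINIT: DurationModel("hist", 3, probs=np.full(10, 0.1)),
            EINT: DurationModel("hist", 3, probs=np.full(10, 0.1)),
            ETERM: DurationModel("hist", 3, probs=np.full(10, 0.1)),
            ESNGL: DurationModel("hist", 6, probs=np.full(25, 1 / 25.0)),
        },
        donor_pwm=base.donor_pwm,
        acceptor_pwm=base.acceptor_pwm,
        start_pwm=spec.start_pwm,
        stop_probs={"TAA": 0.3, "TAG": 0.2, "TGA": 0.5},
        coding=spec.coding,
        noncoding=spec.noncoding,
        pseudocount=1.0,
    )


# ---------------------------------------------------------------------------
# genome fixtures


@dataclass
class FixtureConfig:
    seed: int = 0
    genome_length: int = 3000
    gene_count: int | None = None
    read_length: int = 75
    junction_coverage: int = 12
    error_free: bool = True
    flank: int = 100
    sequence_id: str = "chr_sim"


def make_genome(
    config: FixtureConfig, spec: GhmmSpec | None = None, out_dir: str | Path | None = None
) -> tuple[dict[str, str], list[Transcript]]:
    """Sample a toy genome with embedded genes and its truth annotation.

    With ``gene_count`` set, the sampled sequence is regrown (deterministic
    in the seed) until it holds at least that many genes, then truncated
    shortly after the last wanted gene.  Writes ``genome.fa``/``truth.gtf``
    when ``out_dir`` is given.
    """
    spec = spec or fixture_spec()
    length = config.genome_length
    for _ in range(12):
        seq, transcripts, _ = sample_with_paths(
            spec, length, config.seed, sequence_id=config.sequence_id
        )
        if config.gene_count is None or len(transcripts) >= config.gene_count:
            break
        length = int(length * 1.6)
    if config.gene_count is not None:
        if len(transcripts) < config.gene_count:
            raise RuntimeError("could not sample the requested gene count")
        transcripts = transcripts[: config.gene_count]
        cut = min(len(seq), transcripts[-1].span.end + 150)
        seq = seq[:cut]
    genome = {config.sequence_id: seq}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iso_io.write_fasta(genome, out / "genome.fa")
        iso_io.write_gtf(transcripts, out / "truth.gtf")
    return genome, transcripts


# ---------------------------------------------------------------------------
# read fixtures


@dataclass
class ReadSet:
    records: list
    mature_index: dict
    truth_jc: dict  # junction key -> JC at the generating L
    L: int

    def target_lengths(self) -> dict:
        return {tid: len(m) for tid, m in self.mature_index.items()}


def make_reads(
    transcripts: Sequence[Transcript],
    genome: Mapping[str, str],
    config: FixtureConfig,
    L: int = 10,
    coverage_overrides: Mapping[tuple, int] | None = None,
    tile: bool = True,
    dataset_tag: str = "ds",
) -> ReadSet:
    """Simulate junction-spanning (and optional tiling) reads on matures.

    Junction reads cycle through left-side overhangs ``L, L+2, L+5, ...``
    including the exact-L boundary; ``coverage_overrides`` (keyed by genomic
    junction) can silence or boost individual junctions.  The truth table
    records, per junction, the number of simulated reads that satisfy the
    two-sided >= L rule, pooled across mature transcripts exactly as the
    tally operation pools them.
    """
    if config.read_length < 2 * L:
        raise ValueError("read length must be at least 2*L")
    rng = np.random.default_rng(config.seed + 7919)
    vcfg = ValidationConfig.standard(flank=config.flank)
    mature_index = build_mature(transcripts, genome, vcfg)
    records: list[AlignmentRecord] = []
    n = 0
    for tid in sorted(mature_index):
        mature = mature_index[tid]
        mlen = len(mature)
        for off, key in mature.junctions:
            cov = config.junction_coverage
            if coverage_overrides and key in coverage_overrides:
                cov = coverage_overrides[key]
            for i in range(cov):
                over_left = L + (0, 2, 5, 9)[i % 4]
                s = off - over_left
                if s < 0 or s + config.read_length > mlen:
                    continue
                n += 1
                mism = 0 if config.error_free or n % 5 else 1
                records.append(
                    AlignmentRecord(
                        read_id=f"{dataset_tag}.j{n}",
                        target_id=tid,
                        target_start=s,
                        aligned_length=config.read_length,
                        mismatches=mism,
                    )
                )
        if tile:
            step = max(1, config.read_length // 2)
            for s in range(0, max(1, mlen - config.read_length + 1), step):
                n += 1
                records.append(
                    AlignmentRecord(
                        read_id=f"{dataset_tag}.t{n}",
                        target_id=tid,
                        target_start=s,
                        aligned_length=min(config.read_length, mlen - s),
                        mismatches=0,
                    )
                )
    # truth table: brute per-read bookkeeping at the generating L
    truth_jc: dict = {}
    by_target: dict = {}
    for r in records:
        by_target.setdefault(r.target_id, []).append(r)
    for tid, mature in mature_index.items():
        for off, key in mature.junctions:
            truth_jc.setdefault(key, 0)
            for r in by_target.get(tid, []):
                if r.target_start <= off - L and r.target_start + r.aligned_length >= off + L:
                    truth_jc[key] += 1
    return ReadSet(records=records, mature_index=mature_index, truth_jc=truth_jc, L=L)


def perturb_junction(t: Transcript, shift: int = 9, suffix: str = ".decoy") -> Transcript:
    """A decoy isoform: one internal junction moved by ``shift`` nt.

    Used in closed-loop tests: no reads are simulated for the shifted
    junction, so the decoy must come out unvalidated.
    """
    exons = list(t.cds_exons())
    if len(exons) < 2:
        raise ValueError("need a multi-exon transcript to perturb")
    first = exons[0]
    if len(first) <= shift + 3:
        raise ValueError("first exon too short to shift its donor")
    exons[0] = GenomicInterval(first.sequence_id, first.start, first.end - shift, first.strand)
    return Transcript(
        transcript_id=t.transcript_id + suffix,
        gene_id=t.gene_id,
        exons=tuple(exons),
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
        source_tag="ALTSCAN",
    )


# ---------------------------------------------------------------------------
# peptide fixtures


def _random_peptide(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=length))


def make_peptide_table(
    seed: int = 0,
    n_proteins: int = 30,
    p_callable: float = 0.4,
) -> tuple[list[PeptideHit], dict[str, bool]]:
    """Random peptide-hit fixture with closed-form expected calls.

    Each candidate protein is constructed to be a valid novel-protein call
    (two unique peptides, one novel) with probability ``p_callable``;
    otherwise one of the calling criteria is deliberately broken (shared
    peptides, a single unique peptide, or no novel peptide).  Returns the
    hits plus the truth flags per accession.
    """
    rng = np.random.default_rng(seed)
    hits: list[PeptideHit] = []
    truth: dict[str, bool] = {}
    for i in range(n_proteins):
        acc = f"vmc_p{i}"
        callable_ = rng.random() < p_callable
        truth[acc] = bool(callable_)
        if callable_:
            # two peptides unique to this protein, both VMC-only (hence novel)
            hits.append(PeptideHit(_random_peptide(rng), ((VMC, acc),)))
            hits.append(PeptideHit(_random_peptide(rng), ((VMC, acc),)))
        else:
            mode = int(rng.integers(0, 3))
            if mode == 0:  # only one unique peptide
                hits.append(PeptideHit(_random_peptide(rng), ((VMC, acc),)))
            elif mode == 1:  # two peptides, both shared across proteins
                other = f"vmc_p{i}_alt"
                hits.append(PeptideHit(_random_peptide(rng), ((VMC, acc), (VMC, other))))
                hits.append(PeptideHit(_random_peptide(rng), ((VMC, acc), (VMC, other))))
            else:  # two peptides, both also scored against the reference
                hits.append(
                    PeptideHit(_random_peptide(rng), ((VMC, acc), (REFSEQ, f"ref_p{i}")))
                )
                hits.append(
                    PeptideHit(_random_peptide(rng), ((VMC, acc), (REFSEQ, f"ref_p{i}")))
                )
    return hits, truth


def make_annotation_scenario(
    seed: int = 0,
    n_candidates: int = 61,
    n_both: int = 9,
    n_gencode_only: int = 5,
    n_swissprot_only: int = 11,
) -> tuple[list[PeptideHit], list[str], list[str]]:
    """Construct candidate calls plus external DBs with known cross-tab.

    The first ``n_both`` candidates have their novel peptides embedded in
    both external databases, the next ``n_gencode_only`` in one, the next
    ``n_swissprot_only`` in the other; the remainder are absent from both.
    """
    rng = np.random.default_rng(seed)
    hits: list[PeptideHit] = []
    gencode: list[str] = []
    swissprot: list[str] = []
    for i in range(n_candidates):
        acc = f"vmc_c{i}"
        novel = _random_peptide(rng, 14)
        known = _random_peptide(rng, 14)
        hits.append(PeptideHit(novel, ((VMC, acc),)))
        hits.append(PeptideHit(known, ((VMC, acc),)))
        hits.append(PeptideHit(known, ((REFSEQ, f"ref_c{i}"),)))
        pad = lambda: _random_peptide(rng, 20)
        if i < n_both:
            gencode.append(pad() + novel + pad())
            swissprot.append(pad() + novel + pad())
        elif i < n_both + n_gencode_only:
            gencode.append(pad() + novel + pad())
        elif i < n_both + n_gencode_only + n_swissprot_only:
            swissprot.append(pad() + novel + pad())
    return hits, gencode, swissprot
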