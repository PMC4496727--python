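"""RNA-seq splice-junction validation and confidence tiering.

The pipeline mirrors junction-based transcript validation: coding sequences
are extracted with fixed flanks to form *mature transcripts*, reads aligned
to those matures are tallied per splice junction under an (M, L) rule (a
junction is covered iff at least M reads span it with at least L nt on each
side), and novel transcripts are tiered:

* VHC — validated under the stringent rule (and the standard rule) in at
  least one dataset, with at least one novel internal junction (NIJ);
* VMC — validated under the standard rule with at least one NIJ;
* VLC — validated under the standard rule but single-exon or lacking any
  NIJ;
* KNOWN_VALIDATED / UNVALIDATED for reference transcripts and misses.

Multi-exon validation in a dataset requires *all* internal junctions covered
there.  Single-exon transcripts carry no junctions; they are validated when
at least 90% of their CDS bases are covered by at least one read (an
explicit stand-in rule, see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AlignmentRecord, Transcript
from .ghmm import revcomp

logger = logging.getLogger(__name__)

JunctionKey = tuple  # (sequence_id, intron_start, intron_end, strand)


@dataclass
class ValidationConfig:
    """(M, L) junction rule settings plus mature-transcript geometry."""

    flank: int = 100
    L: int = 10
    M: int = 1
    strategy_name: str = "standard"
    max_mismatch: int | None = None
    min_tc: float = 0.0  # optional fraction-of-CDS-covered requirement
    single_exon_min_coverage: float = 0.9

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.strategy_name == "standard":
            if (self.L, self.M) != (10, 1):
                raise ValueError("standard strategy fixes L=10, M=1")
        elif self.strategy_name == "stringent":
            if self.M < 6 or self.L < 8:
                raise ValueError("stringent strategy requires M >= 6 and L >= 8")
        else:
            raise ValueError(f"unknown strategy {self.strategy_name!r}")

    @classmethod
    def standard(cls, **kw) -> "ValidationConfig":
        return cls(strategy_name="standard", L=10, M=1, **kw)

    @classmethod
    def stringent(cls, L: int = 8, M: int = 6, **kw) -> "ValidationConfig":
        return cls(strategy_name="stringent", L=L, M=M, **kw)


@dataclass
class MatureTranscript:
    """A spliced CDS with flanks, plus junction offsets in mature coordinates."""

    transcript_id: str
    sequence: str
    junctions: tuple  # ((mature_offset, junction_key), ...)
    cds_interval: tuple  # (start, end) of the CDS within the mature sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class JunctionEvidence:
    """Read support for one splice junction in one dataset."""

    key: JunctionKey
    jc: int = 0
    is_novel_internal: bool = False


@dataclass
class ValidationVerdict:
    transcript_id: str
    tier: str
    n_datasets_validated: int
    tissue_specific: bool
    per_dataset: dict = field(default_factory=dict)  # dataset -> bool (standard rule)
    datasets_stringent: tuple = ()


def build_mature(
    transcripts: Sequence[Transcript],
    genome: Mapping[str, str],
    config: ValidationConfig | None = None,
) -> dict[str, MatureTranscript]:
    """Extract flank + spliced CDS + flank per transcript.

    Reverse-strand transcripts are reverse-complemented so the mature
    sequence reads 5'->3'.  Flanks extending past the chromosome end are
    truncated with a logged warning.
    """
    config = config or ValidationConfig()
    out: dict[str, MatureTranscript] = {}
    truncated = 0
    for t in transcripts:
        chrom = genome[t.sequence_id]
        exons = t.cds_exons()
        left_start = max(0, exons[0].start - config.flank)
        right_end = min(len(chrom), exons[-1].end + config.flank)
        if exons[0].start - config.flank < 0 or exons[-1].end + config.flank > len(chrom):
            truncated += 1
        left = chrom[left_start : exons[0].start]
        right = chrom[exons[-1].end : right_end]
        cds_parts = [chrom[e.start : e.end] for e in exons]
        plus_seq = left + "".join(cds_parts) + right
        # junction offsets in plus-orientation mature coordinates
        offsets = []
        cum = len(left)
        for i, part in enumerate(cds_parts[:-1]):
            cum += len(part)
            offsets.append((cum, t.internal_junctions()[i]))
        cds_lo, cds_hi = len(left), len(left) + sum(len(p) for p in cds_parts)
        if t.strand == "-":
            total = len(plus_seq)
            seq = revcomp(plus_seq)
            offsets = [(total - off, key) for off, key in offsets][::-1]
            cds_lo, cds_hi = total - cds_hi, total - cds_lo
        else:
            seq = plus_seq
        out[t.transcript_id] = MatureTranscript(
            transcript_id=t.transcript_id,
            sequence=seq.upper(),
            junctions=tuple(offsets),
            cds_interval=(cds_lo, cds_hi),
        )
    if truncated:
        logger.warning("build_mature: %d flanks truncated at chromosome ends", truncated)
    return out


def tally_junctions(
    alignments: Sequence[AlignmentRecord],
    mature_index: Mapping[str, MatureTranscript],
    config: ValidationConfig | None = None,
) -> dict[JunctionKey, JunctionEvidence]:
    """Count junction-spanning reads under the (M, L) rule.

    A read [s, s+len) on a mature transcript counts for the junction at
    mature offset j iff ``s <= j - L`` and ``s + len >= j + L`` (at least L
    nt on each side).  Counts for the same genomic junction occurring in
    several mature transcripts are pooled.  Alignments naming unknown
    matures are skipped with a logged count.
    """
    config = config or ValidationConfig()
    by_target: dict[str, list[AlignmentRecord]] = {}
    skipped = 0
    for a in alignments:
        if a.target_id not in mature_index:
            skipped += 1
            continue
        if config.max_mismatch is not None and a.mismatches > config.max_mismatch:
            continue
        by_target.setdefault(a.target_id, []).append(a)
    if skipped:
        logger.info("tally_junctions: skipped %d alignments to unknown targets", skipped)
    out: dict[JunctionKey, JunctionEvidence] = {}
    L = config.L
    for tid, mature in mature_index.items():
        alns = by_target.get(tid, [])
        for off, key in mature.junctions:
            ev = out.setdefault(key, JunctionEvidence(key=key))
            for a in alns:
                if a.target_start <= off - L and a.target_start + a.aligned_length >= off + L:
                    ev.jc += 1
    return out


def cds_coverage(
    alignments: Sequence[AlignmentRecord],
    mature_index: Mapping[str, MatureTranscript],
    config: ValidationConfig | None = None,
) -> dict[str, float]:
    """Fraction of CDS bases covered by >= 1 read, per transcript."""
    config = config or ValidationConfig()
    by_target: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.target_id in mature_index:
            if config.max_mismatch is not None and a.mismatches > config.max_mismatch:
                continue
            by_target.setdefault(a.target_id, []).append(a)
    out: dict[str, float] = {}
    for tid, mature in mature_index.items():
        lo, hi = mature.cds_interval
        if hi <= lo:
            out[tid] = 0.0
            continue
        covered = np.zeros(hi - lo, dtype=bool)
        for a in by_target.get(tid, []):
            s = max(a.target_start, lo)
            e = min(a.target_start + a.aligned_length, hi)
            if s < e:
                covered[s - lo : e - lo] = True
        out[tid] = float(covered.mean())
    return out


def known_junction_set(known: Sequence[Transcript]) -> set:
    out: set = set()
    for t in known:
        out.update(t.internal_junctions())
    return out


def mark_novel_junctions(
    evidence: Mapping[JunctionKey, JunctionEvidence], known: Sequence[Transcript]
) -> None:
    """Set the NIJ flag on junction evidence in place."""
    known_set = known_junction_set(known)
    for key, ev in evidence.items():
        ev.is_novel_internal = key not in known_set


def _validated_in_dataset(
    t: Transcript,
    evidence: Mapping[JunctionKey, JunctionEvidence],
    coverage: Mapping[str, float] | None,
    config: ValidationConfig,
) -> bool:
    if not t.cds_exons():
        raise ValueError(f"{t.transcript_id}: transcript with no exons")
    juncs = t.internal_junctions()
    if juncs:
        ok = all(
            key in evidence and evidence[key].jc >= config.M for key in juncs
        )
        if ok and config.min_tc > 0 and coverage is not None:
            ok = coverage.get(t.transcript_id, 0.0) >= config.min_tc
        return ok
    if coverage is None:
        return False
    return coverage.get(t.transcript_id, 0.0) >= config.single_exon_min_coverage


def validate_transcripts(
    transcripts: Sequence[Transcript],
    known: Sequence[Transcript],
    evidence_standard: Mapping[str, Mapping[JunctionKey, JunctionEvidence]],
    evidence_stringent: Mapping[str, Mapping[JunctionKey, JunctionEvidence]] | None = None,
    config_standard: ValidationConfig | None = None,
    config_stringent: ValidationConfig | None = None,
    coverage_standard: Mapping[str, Mapping[str, float]] | None = None,
    tissue_specific_max: int = 5,
) -> list[ValidationVerdict]:
    """Assign VHC/VMC/VLC/KNOWN_VALIDATED/UNVALIDATED tiers.

    ``evidence_standard``/``evidence_stringent`` map dataset names to the
    junction tallies computed with the matching configs.  A transcript whose
    CDS coordinates occur in ``known`` is treated as a reference transcript;
    all others are novel candidates.  VHC is defined hierarchically (a VHC
    transcript also meets the VMC criteria).  Tissue specificity means
    validated in at least one but fewer than ``tissue_specific_max`` datasets.
    """
    config_standard = config_standard or ValidationConfig.standard()
    config_stringent = config_stringent or ValidationConfig.stringent()
    known_keys = {t.cds_key() for t in known}
    nij = known_junction_set(known)
    verdicts: list[ValidationVerdict] = []
    datasets = sorted(evidence_standard)
    for t in transcripts:
        per_ds = {}
        for ds in datasets:
            cov = coverage_standard.get(ds) if coverage_standard else None
            per_ds[ds] = _validated_in_dataset(
                t, evidence_standard[ds], cov, config_standard
            )
        std_ok = [ds for ds, v in per_ds.items() if v]
        str_ok = []
        if evidence_stringent is not None:
            for ds in sorted(evidence_stringent):
                if t.internal_junctions() and _validated_in_dataset(
                    t, evidence_stringent[ds], None, config_stringent
                ):
                    str_ok.append(ds)
        is_known = t.cds_key() in known_keys or t.source_tag == "KNOWN"
        has_nij = any(key not in nij for key in t.internal_junctions())
        if is_known:
            tier = "KNOWN_VALIDATED" if std_ok else "UNVALIDATED"
        elif std_ok and str_ok and has_nij:
            tier = "VHC"
        elif std_ok and has_nij:
            tier = "VMC"
        elif std_ok:
            tier = "VLC"
        else:
            tier = "UNVALIDATED"
        n_val = len(std_ok)
        verdicts.append(
            ValidationVerdict(
                transcript_id=t.transcript_id,
                tier=tier,
                n_datasets_validated=n_val,
                tissue_specific=1 <= n_val < tissue_specific_max,
                per_dataset=per_ds,
                datasets_stringent=tuple(str_ok),
            )
        )
    return verdicts


def saturation_curve(
    validated_sets: Mapping[str, set],
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Mean number of newly validated transcripts per added dataset.

    Dataset orderings are drawn uniformly at random; for each prefix length
    the count of transcripts validated by the newly added dataset but by none
    of the earlier ones is averaged over orderings.  Deterministic under the
    seed.
    """
    names = sorted(validated_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 datasets")
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(names))
    for _ in range(n_permutations):
        order = rng.permutation(len(names))
        seen: set = set()
        for step, idx in enumerate(order):
            new = validated_sets[names[idx]] - seen
            totals[step] += len(new)
            seen |= validated_sets[names[idx]]
    return totals / n_permutations


def pcr_panel_summary(
    outcomes: Mapping[str, bool], tiers: Mapping[str, str]
) -> dict[str, dict]:
    """Per-tier success rates of a PCR validation panel.

    ``outcomes`` maps assayed transcript ids to validated-in-at-least-one-
    sample flags; ``tiers`` maps the same ids to their tier.  Rates are
    reported both as fractions and as percentages rounded to one decimal.
    """
    if not outcomes:
        raise ValueError("no assay outcomes provided")
    out: dict[str, dict] = {}
    for tid, ok in outcomes.items():
        tier = tiers[tid]
        rec = out.setdefault(tier, {"assayed": 0, "validated": 0})
        rec["assayed"] += 1
        rec["validated"] += int(ok)
    for rec in out.values():
        rec["rate"] = rec["validated"] / rec["assayed"]
        rec["percent"] = round(100.0 * rec["validated"] / rec["assayed"], 1)
    return out
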