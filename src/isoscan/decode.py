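"""k-best (list) Viterbi decoding of the gene GHMM, with post-filters.

The decoder keeps the top-N highest-scoring partial paths per dynamic-
programming cell, where a cell is (segment end position, state, reading-frame
phase, split-codon bases).  Because future scores depend only on the cell
key, any globally top-N path has a top-N prefix in every cell it passes
through, so per-cell candidate lists of size N are lossless.  Candidate exon
and intron boundaries are restricted to signal anchors (ATG, GT, AG, stop
codons), which keeps the search sparse.

Tie-breaking is deterministic: equal-scoring paths are ordered
lexicographically by their (state, segment-start) encoding, so the top-k list
for k < N is always a prefix of the top-N list.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, Transcript
from .ghmm import (
    EINIT,
    EINT,
    ESNGL,
    ETERM,
    INTRON,
    LOG_QUARTER,
    MIN_EXON,
    N,
    NEG_INF,
    STOP_CODONS,
    GhmmSpec,
    Segment,
    encode,
    revcomp,
)

logger = logging.getLogger(__name__)

_STATE_RANK = {N: 0, ESNGL: 1, EINIT: 2, INTRON: 3, EINT: 4, ETERM: 5}


@dataclass
class DecoderConfig:
    """Decoder settings; defaults follow the published run configuration."""

    top_n: int = 250
    padding: int = 5000
    min_intron: int = 20
    max_intron: int = 500  # decode-time cap on intron length (DP lookback)
    max_intergenic: int | None = None  # optional cap, None = unbounded

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.min_intron < 1:
            raise ValueError("min_intron must be >= 1")


@dataclass(frozen=True)
class ScoredPath:
    """One decoded segmentation; rank 1 is the standard Viterbi path."""

    rank: int
    log_score: float
    path: tuple
    transcripts: tuple

    @property
    def is_suboptimal(self) -> bool:
        return self.rank > 1


class _Decoder:
    def __init__(self, spec: GhmmSpec, sequence: str, config: DecoderConfig):
        self.spec = spec
        self.seq = sequence.upper()
        self.enc = encode(self.seq)
        self.cfg = config
        self.L = len(self.seq)
        self.k = spec.order
        self.min_intron = max(config.min_intron, spec.min_intron)
        self._precompute()
        # entry store: parallel lists, entry 0 is the virtual root
        self.e_score: list[float] = [0.0]
        self.e_parent: list[int] = [-1]
        self.e_state: list[str] = [""]
        self.e_start: list[int] = [0]
        self._enc_cache: dict[int, tuple] = {0: ()}
        # cells: pos -> {key: [contribs]}; key = (state, phase, dangling)
        self.cells: list[dict] = [dict() for _ in range(self.L + 1)]
        self.final: dict = {}  # finalized: (pos, key) -> (ids, scores)

    # -- precomputation -----------------------------------------------------

    def _precompute(self) -> None:
        seq, enc, L, k = self.seq, self.enc, self.L, self.k
        spec = self.spec
        nc = np.zeros(L)
        for p in range(k, L):
            nc[p] = spec.noncoding.logp_base(enc, p, 0)
        self.NC = np.concatenate([[0.0], np.cumsum(nc)])
        # coding cumsums per residue class r: base at p scored with codon
        # position (p + r) % 3
        self.CR = []
        for r in range(3):
            arr = np.zeros(L)
            for p in range(k, L):
                chain = spec.coding[(p + r) % 3]
                b = enc[p]
                if b < 0:
                    arr[p] = LOG_QUARTER
                else:
                    ctx = chain.context_index(enc, p)
                    arr[p] = LOG_QUARTER if ctx < 0 else float(chain.log_probs[ctx, b])
            self.CR.append(np.concatenate([[0.0], np.cumsum(arr)]))
        # anchors
        self.atg = [p for p in range(1, L - 2) if seq[p : p + 3] == "ATG"]
        self.donors = [p for p in range(L - 1) if seq[p : p + 2] == "GT"]
        self.acceptors = [p for p in range(2, L + 1) if seq[p - 2 : p] == "AG"]
        self.stops_by_class = {m: [] for m in range(3)}
        for p in range(L - 2):
            if seq[p : p + 3] in STOP_CODONS:
                self.stops_by_class[p % 3].append(p)
        self.donor_score = {d: spec.donor_pwm.score(enc, d) for d in self.donors}
        self.acceptor_score = {a: spec.acceptor_pwm.score(enc, a) for a in self.acceptors}
        self.start_score = {j: spec.start_pwm.score(enc, j) for j in self.atg}
        self.log_stop = {
            c: math.log(spec.stop_probs[c]) if spec.stop_probs.get(c, 0) > 0 else NEG_INF
            for c in STOP_CODONS
        }

    def _noncode(self, j: int, i: int) -> float:
        k = self.k
        cut = min(i, j + k)
        return (cut - j) * LOG_QUARTER + float(self.NC[i] - self.NC[cut])

    def _coding(self, j: int, i: int, phase: int) -> float:
        # codon position of base p is (phase + p - j) % 3 = (p + r) % 3
        r = (phase - j) % 3
        k = self.k
        cut = min(i, j + k)
        return (cut - j) * LOG_QUARTER + float(self.CR[r][i] - self.CR[r][cut])

    def _first_stop(self, cls: int, lo: int) -> int | None:
        lst = self.stops_by_class[cls]
        i = bisect.bisect_left(lst, lo)
        return lst[i] if i < len(lst) else None

    # -- contribution plumbing ---------------------------------------------

    def _contribute(self, pos: int, key: tuple, src: tuple, state: str, j: int, scalar: float) -> None:
        if scalar == NEG_INF or math.isinf(scalar):
            return
        ids, scores = src
        self.cells[pos].setdefault(key, []).append((ids, scores + scalar, state, j))

    def _encoding(self, eid: int) -> tuple:
        enc = self._enc_cache.get(eid)
        if enc is None:
            enc = self._encoding(self.e_parent[eid]) + (
                (_STATE_RANK[self.e_state[eid]], self.e_start[eid]),
            )
            self._enc_cache[eid] = enc
        return enc

    def _finalize(self, contribs: list) -> tuple:
        """Merge contributions into the top-N entry list for a cell."""
        scores = np.concatenate([c[1] for c in contribs])
        parents = np.concatenate([c[0] for c in contribs])
        meta = np.concatenate(
            [np.full(len(c[0]), ci, dtype=np.int64) for ci, c in enumerate(contribs)]
        )
        order = np.argsort(-scores, kind="stable")
        n = self.cfg.top_n
        # deterministic tie-break: within equal scores, lexicographic on the
        # (state, start) encoding of the full candidate path
        order = list(order)
        out = []
        i = 0
        while i < len(order) and len(out) < n:
            jx = i
            while jx < len(order) and scores[order[jx]] == scores[order[i]]:
                jx += 1
            group = order[i:jx]
            if len(group) > 1:
                group.sort(
                    key=lambda ix: self._encoding(int(parents[ix]))
                    + ((_STATE_RANK[contribs[meta[ix]][2]], contribs[meta[ix]][3]),)
                )
            out.extend(group[: n - len(out)])
            i = jx
        ids = []
        kept_scores = []
        for ix in out:
            c = contribs[meta[ix]]
            self.e_score.append(float(scores[ix]))
            self.e_parent.append(int(parents[ix]))
            self.e_state.append(c[2])
            self.e_start.append(c[3])
            ids.append(len(self.e_score) - 1)
            kept_scores.append(float(scores[ix]))
        return np.array(ids, dtype=np.int64), np.array(kept_scores)

    # -- extensions ---------------------------------------------------------

    def _extend_intergenic(self, src: tuple, j: int, from_root: bool, prev_state: str) -> None:
        spec, cfg = self.spec, self.cfg
        if N not in spec.durations:
            return
        trans = 0.0 if from_root else spec.log_trans(prev_state, N)
        row = spec.allowed_next(N)
        targets = [i for i in self.atg if i > j]
        cap = cfg.max_intergenic
        for i in targets + [self.L]:
            d = i - j
            if d < 1 or (cap is not None and d > cap and i != self.L):
                continue
            scalar = trans + spec.durations[N].logp(d) + self._noncode(j, i)
            if i == self.L:
                self._contribute(i, (N,), src, N, j, scalar)
            else:
                if ESNGL in row or EINIT in row:
                    self._contribute(i, (N,), src, N, j, scalar)

    def _extend_gene_start(self, src: tuple, i: int) -> None:
        """From an intergenic cell ending at an ATG: start Esngl or Einit."""
        spec = self.spec
        row = spec.allowed_next(N)
        start_bonus = self.start_score.get(i, NEG_INF)
        if ESNGL in row and ESNGL in spec.durations:
            p = self._first_stop(i % 3, i + 3)
            if p is not None and p + 3 <= self.L:
                d = p + 3 - i
                scalar = (
                    spec.log_trans(N, ESNGL)
                    + spec.durations[ESNGL].logp(d)
                    + start_bonus
                    + self._coding(i + 3, p, 0)
                    + self.log_stop[self.seq[p : p + 3]]
                )
                self._contribute(i + d, (ESNGL,), src, ESNGL, i, scalar)
        if EINIT in row and EINIT in spec.durations:
            dur = spec.durations[EINIT]
            hi = dur.hist_max if dur.kind == "hist" else self.L
            p = self._first_stop(i % 3, i)
            stop_limit = p + 2 if p is not None else self.L  # exon must end <= p+2
            lo_end = i + max(MIN_EXON, dur.min_len)
            hi_end = min(i + hi, stop_limit, self.L - self.min_intron)
            for d_pos in self._donors_between(lo_end, hi_end):
                scalar = (
                    spec.log_trans(N, EINIT)
                    + dur.logp(d_pos - i)
                    + start_bonus
                    + self._coding(i + 3, d_pos, 0)
                )
                self._contribute(d_pos, (EINIT, (d_pos - i) % 3), src, EINIT, i, scalar)

    def _donors_between(self, lo: int, hi: int) -> list:
        i = bisect.bisect_left(self.donors, lo)
        out = []
        while i < len(self.donors) and self.donors[i] <= hi:
            out.append(self.donors[i])
            i += 1
        return out

    def _extend_intron(self, src: tuple, j: int, state: str, phase: int) -> None:
        spec = self.spec
        if INTRON not in spec.durations:
            return
        trans = spec.log_trans(state, INTRON)
        dang = self.seq[j - phase : j] if phase else ""
        donor = self.donor_score.get(j, NEG_INF)
        lo = j + self.min_intron
        hi = min(j + self.cfg.max_intron, self.L - MIN_EXON)
        ia = bisect.bisect_left(self.acceptors, lo)
        while ia < len(self.acceptors) and self.acceptors[ia] <= hi:
            a = self.acceptors[ia]
            ia += 1
            scalar = (
                trans
                + spec.durations[INTRON].logp(a - j)
                + self._noncode(j + 6, a - 13)
                + donor
                + self.acceptor_score[a]
            )
            self._contribute(a, (INTRON, phase, dang), src, INTRON, j, scalar)

    def _extend_coding(self, src: tuple, a: int, phase: int, dang: str) -> None:
        """From an intron cell ending at acceptor ``a``: internal or terminal exon."""
        spec = self.spec
        # split codon spanning the junction just crossed
        if phase:
            codon = dang + self.seq[a : a + 3 - phase]
            if len(codon) == 3 and codon in STOP_CODONS:
                return
        p0 = a + ((3 - phase) % 3)
        p_first = self._first_stop(p0 % 3, p0)
        row = spec.allowed_next(INTRON)
        if EINT in row and EINT in spec.durations:
            dur = spec.durations[EINT]
            hi = dur.hist_max if dur.kind == "hist" else self.L
            stop_limit = p_first + 2 if p_first is not None else self.L
            lo_end = a + max(MIN_EXON, dur.min_len)
            hi_end = min(a + hi, stop_limit, self.L - self.min_intron)
            trans = spec.log_trans(INTRON, EINT)
            for d_pos in self._donors_between(lo_end, hi_end):
                scalar = trans + dur.logp(d_pos - a) + self._coding(a, d_pos, phase)
                self._contribute(
                    d_pos,
                    (EINT, (phase + d_pos - a) % 3),
                    src,
                    EINT,
                    a,
                    scalar,
                )
        if ETERM in row and ETERM in spec.durations and p_first is not None:
            e = p_first + 3
            d = e - a
            if d >= MIN_EXON and e <= self.L:
                scalar = (
                    spec.log_trans(INTRON, ETERM)
                    + spec.durations[ETERM].logp(d)
                    + self._coding(a, e - 3, phase)
                    + self.log_stop[self.seq[e - 3 : e]]
                )
                self._contribute(e, (ETERM,), src, ETERM, a, scalar)

    # -- main loop ----------------------------------------------------------

    def run(self) -> list:
        root = (np.array([0], dtype=np.int64), np.array([0.0]))
        self._extend_intergenic(root, 0, from_root=True, prev_state="")
        for pos in range(1, self.L + 1):
            for key, contribs in sorted(self.cells[pos].items()):
                cell = self._finalize(contribs)
                if pos == self.L:
                    self.final[key] = cell
                    continue
                state = key[0]
                if state == N:
                    self._extend_gene_start(cell, pos)
                elif state in (EINIT, EINT):
                    self._extend_intron(cell, pos, state, key[1])
                elif state == INTRON:
                    self._extend_coding(cell, pos, key[1], key[2])
                elif state in (ETERM, ESNGL):
                    self._extend_intergenic(cell, pos, from_root=False, prev_state=state)
            self.cells[pos] = {}
        # merge terminal cells (paths may end intergenic or at a gene end)
        contribs = []
        for key, (ids, scores) in sorted(self.final.items()):
            if key[0] in (N, ESNGL, ETERM):
                contribs.append((ids, scores.copy(), "_end", self.L))
        if not contribs:
            return []
        merged = self._merge_final(contribs)
        return merged

    def _merge_final(self, contribs: list) -> list:
        scores = np.concatenate([c[1] for c in contribs])
        ids = np.concatenate([c[0] for c in contribs])
        order = list(np.argsort(-scores, kind="stable"))
        out = []
        i = 0
        n = self.cfg.top_n
        while i < len(order) and len(out) < n:
            jx = i
            while jx < len(order) and scores[order[jx]] == scores[order[i]]:
                jx += 1
            group = order[i:jx]
            if len(group) > 1:
                group.sort(key=lambda ix: self._encoding(int(ids[ix])))
            out.extend(group[: n - len(out)])
            i = jx
        return [(float(scores[ix]), int(ids[ix])) for ix in out]

    def path_of(self, eid: int) -> tuple:
        chain = []
        while eid > 0:
            chain.append((self.e_state[eid], self.e_start[eid]))
            eid = self.e_parent[eid]
        chain.reverse()
        segs = []
        for idx, (state, start) in enumerate(chain):
            end = chain[idx + 1][1] if idx + 1 < len(chain) else self.L
            segs.append(Segment(state, end - start))
        return tuple(segs)


def _transcripts_from_path(
    path: tuple, sequence_id: str, origin: int, rank: int, id_prefix: str
) -> tuple:
    """Extract gene structures (one Transcript per gene) from a segmentation."""
    out = []
    pos = origin
    exons: list[GenomicInterval] = []
    gene_no = 0
    for seg in path:
        end = pos + seg.length
        if seg.state in (EINIT, EINT, ETERM, ESNGL):
            exons.append(GenomicInterval(sequence_id, pos, end, "+"))
            if seg.state in (ETERM, ESNGL):
                gene_no += 1
                tid = f"{id_prefix}r{rank}.g{gene_no}"
                out.append(
                    Transcript(
                        transcript_id=tid,
                        gene_id=tid,
                        exons=tuple(exons),
                        cds_start=exons[0].start,
                        cds_end=exons[-1].end,
                        source_tag="ALTSCAN",
                    )
                )
                exons = []
        pos = end
    return tuple(out)


def kbest_decode(
    spec: GhmmSpec,
    sequence: str,
    config: DecoderConfig | None = None,
    sequence_id: str = "seq",
    origin: int = 0,
    id_prefix: str = "p.",
) -> list[ScoredPath]:
    """Return the top-N distinct state paths for a (forward-strand) sequence.

    Entry 1 is the standard Viterbi path; scores are non-increasing with
    rank; returns fewer than N entries when fewer legal paths exist, and an
    empty list when no legal segmentation exists at all.
    """
    config = config or DecoderConfig()
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    dec = _Decoder(spec, sequence, config)
    ranked = dec.run()
    out = []
    for rank, (score, eid) in enumerate(ranked, start=1):
        path = dec.path_of(eid)
        out.append(
            ScoredPath(
                rank=rank,
                log_score=score,
                path=path,
                transcripts=_transcripts_from_path(
                    path, sequence_id, origin, rank, id_prefix
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# post-filters


def _has_complete_orf(t: Transcript, genome: dict | None) -> bool:
    if t.cds_length() % 3 != 0 or t.cds_length() < 6:
        return False
    if genome is None:
        return True
    seq = genome[t.sequence_id]
    cds = "".join(seq[e.start : e.end] for e in t.cds_exons())
    if t.strand == "-":
        cds = revcomp(cds)
    cds = cds.upper()
    if not cds.startswith("ATG") or cds[-3:] not in STOP_CODONS:
        return False
    return all(cds[c : c + 3] not in STOP_CODONS for c in range(3, len(cds) - 3, 3))


def postfilter(
    paths: list[ScoredPath],
    config: DecoderConfig | None = None,
    genome: dict | None = None,
) -> list[Transcript]:
    """Apply the published post-prediction filters to decoded paths.

    Keeps complete ORFs only, drops transcripts containing an intron shorter
    than the minimum, and deduplicates by exact CDS coordinates keeping the
    highest-scoring representative.  When ``genome`` is provided the ORF test
    is sequence-level (ATG / terminal stop / no internal stop); otherwise the
    structural criteria (CDS length divisible by three) are checked.
    """
    config = config or DecoderConfig()
    seen: set = set()
    out: list[Transcript] = []
    for sp in sorted(paths, key=lambda p: p.rank):
        for t in sp.transcripts:
            if any(e - s < config.min_intron for s, e in t.introns()):
                continue
            if not _has_complete_orf(t, genome):
                continue
            key = t.cds_key()
            if key in seen:
                continue
            seen.add(key)
            out.append(t)
    return out


def cluster_loci(transcripts: list[Transcript]) -> dict[str, list[Transcript]]:
    """Single-linkage clustering of same-sequence, same-strand transcripts
    whose exonic extents overlap by >= 1 bp; locus ids are deterministic
    (sequence, strand, leftmost coordinate)."""
    groups: dict = {}
    for t in transcripts:
        groups.setdefault((t.sequence_id, t.strand), []).append(t)
    out: dict[str, list[Transcript]] = {}
    for (seq_id, strand), ts in sorted(groups.items()):
        ts = sorted(ts, key=lambda t: (t.span.start, t.span.end, t.transcript_id))
        cluster: list[Transcript] = []
        cluster_end = -1
        for t in ts:
            if cluster and t.span.start < cluster_end:
                cluster.append(t)
                cluster_end = max(cluster_end, t.span.end)
            else:
                if cluster:
                    lid = f"{seq_id}:{strand}:{cluster[0].span.start}"
                    out[lid] = cluster
                cluster = [t]
                cluster_end = t.span.end
        if cluster:
            lid = f"{seq_id}:{strand}:{cluster[0].span.start}"
            out[lid] = cluster
    return out


def evaluate_predictions(
    predicted: list[Transcript], reference: list[Transcript]
) -> dict:
    """Gene- and transcript-level sensitivity/specificity by exact CDS match.

    A transcript matches when sequence, strand and the ordered CDS exon
    coordinates are identical.  A gene matches when at least one of its
    transcripts matches.
    """
    if not reference:
        raise ValueError("reference set is empty")
    ref_keys = {t.cds_key() for t in reference}
    pred_keys = {t.cds_key() for t in predicted}
    ref_matched = [t for t in reference if t.cds_key() in pred_keys]
    pred_matched = [t for t in predicted if t.cds_key() in ref_keys]
    ref_genes = {t.gene_id for t in reference}
    pred_genes = {t.gene_id for t in predicted}
    ref_genes_hit = {t.gene_id for t in ref_matched}
    pred_genes_hit = {t.gene_id for t in pred_matched}
    return {
        "transcript_sn": len(ref_matched) / len(reference),
        "transcript_sp": len(pred_matched) / len(predicted) if predicted else 0.0,
        "gene_sn": len(ref_genes_hit) / len(ref_genes),
        "gene_sp": len(pred_genes_hit) / len(pred_genes) if pred_genes else 0.0,
        "n_transcripts_matched": len(ref_matched),
        "n_genes_matched": len(ref_genes_hit),
    }


# ---------------------------------------------------------------------------
# region-level prediction (padding + strand handling)


def predict_region(
    spec: GhmmSpec,
    genome: dict,
    region: GenomicInterval,
    config: DecoderConfig | None = None,
    both_strands: bool = False,
) -> list[Transcript]:
    """Decode a padded candidate region and map results back to genome
    coordinates.  Reverse-strand genes are found by decoding the reverse
    complement with the forward model and mirroring coordinates."""
    config = config or DecoderConfig()
    chrom = genome[region.sequence_id]
    s = max(0, region.start - config.padding)
    e = min(len(chrom), region.end + config.padding)
    sub = chrom[s:e]
    strands = ("+", "-") if both_strands else (region.strand,)
    out: list[Transcript] = []
    for strand in strands:
        dseq = sub if strand == "+" else revcomp(sub)
        paths = kbest_decode(
            spec,
            dseq,
            config,
            sequence_id=region.sequence_id,
            origin=0,
            id_prefix=f"{region.sequence_id}:{s}{strand}|",
        )
        kept = postfilter(paths, config, genome={region.sequence_id: dseq})
        for t in kept:
            if strand == "+":
                exons = tuple(
                    GenomicInterval(region.sequence_id, s + x.start, s + x.end, "+")
                    for x in t.exons
                )
            else:
                n = len(sub)
                exons = tuple(
                    sorted(
                        GenomicInterval(
                            region.sequence_id, s + n - x.end, s + n - x.start, "-"
                        )
                        for x in t.exons
                    )
                )
            out.append(
                Transcript(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    exons=exons,
                    cds_start=exons[0].start,
                    cds_end=exons[-1].end,
                    source_tag="ALTSCAN",
                )
            )
    logger.info(
        "predict_region %s:%d-%d: %d transcripts kept", region.sequence_id, region.start, region.end, len(out)
    )
    return out
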