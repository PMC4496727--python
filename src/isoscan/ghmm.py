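"""Generalized (explicit-duration) hidden Markov model of gene structure.

The model is GENSCAN-like: an intergenic state ``N``, exon states ``Einit``,
``Eint``, ``Eterm`` and ``Esngl`` (single-exon gene), and an intron state
``I`` whose reading-frame phase and split-codon bases are tracked as path
bookkeeping rather than as separate state copies.  Emissions combine

* a homogeneous k-order Markov chain for noncoding sequence (intergenic and
  intron interiors),
* a 3-periodic k-order Markov chain for coding sequence (one chain per codon
  position; the terminal stop codon is scored by a separate stop-codon
  distribution),
* position weight matrices over fixed signal windows — the first 6 intron
  bases (donor, GT required), the last 13 intron bases (acceptor, AG
  required) and the ATG start triplet; window bases are emitted by the PWM
  and are excluded from the content chains, so every base is emitted by
  exactly one submodel and the total probability over all paths of a
  sequence never exceeds one.

Hard constraints make illegal gene structures impossible rather than merely
improbable: exons must respect the ORF (ATG start, in-frame terminal stop, no
in-frame internal stop, including codons split across introns), introns must
start GT, end AG and respect the minimum intron length, and every exon is at
least 3 nt so that split-codon bases are always a contiguous suffix of the
upstream exon.

All arithmetic is in log space.  Within a segment the first min(k, length)
bases are scored uniformly (1/4 each), which makes segment scores independent
of neighbouring segments; this is what allows the decoder's dynamic program
to treat segments as self-contained.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, Transcript

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = ("TAA", "TAG", "TGA")
LOG_QUARTER = math.log(0.25)
NEG_INF = float("-inf")

# state names
N, EINIT, EINT, ETERM, ESNGL, INTRON = "N", "Einit", "Eint", "Eterm", "Esngl", "I"
EXON_STATES = (EINIT, EINT, ETERM, ESNGL)
TERMINAL_STATES = (N, ESNGL, ETERM)
MIN_EXON = 3  # keeps split-codon bases a contiguous genomic suffix

# signal window geometry (window start relative to the anchor, window width)
# each window lies wholly inside its own segment so every base is emitted by
# exactly one submodel (content chains never score signal-window bases)
DONOR_OFFSET, DONOR_WIDTH = 0, 6  # anchor = first intron base (G of GT)
ACCEPTOR_OFFSET, ACCEPTOR_WIDTH = -13, 13  # anchor = first base after the intron
START_OFFSET, START_WIDTH = 0, 3  # anchor = A of ATG


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; non-ACGT bases become -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# submodels


@dataclass
class MarkovChain:
    """k-order Markov chain over ACGT; ``probs[context, base]`` row-normalized."""

    order: int
    probs: np.ndarray  # shape (4**order, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4**self.order, 4):
            raise ValueError("Markov chain table has wrong shape")
        with np.errstate(divide="ignore"):
            self.log_probs = np.log(self.probs)

    def context_index(self, enc: np.ndarray, pos: int) -> int:
        """Base-4 code of enc[pos-order:pos], or -1 if invalid/ambiguous."""
        if pos < self.order:
            return -1
        idx = 0
        for p in range(pos - self.order, pos):
            b = enc[p]
            if b < 0:
                return -1
            idx = idx * 4 + int(b)
        return idx

    def logp_base(self, enc: np.ndarray, pos: int, seg_start: int) -> float:
        """Log-probability of the base at ``pos`` inside a segment starting at
        ``seg_start`` (first ``order`` bases of the segment are uniform)."""
        if pos - seg_start < self.order:
            return LOG_QUARTER
        b = enc[pos]
        if b < 0:
            return LOG_QUARTER
        ctx = self.context_index(enc, pos)
        if ctx < 0:
            return LOG_QUARTER
        return float(self.log_probs[ctx, b])

    def logp_segment(self, enc: np.ndarray, start: int, end: int) -> float:
        return sum(self.logp_base(enc, p, start) for p in range(start, end))

    def sample_base(self, rng: np.random.Generator, context: str) -> str:
        k = self.order
        ctx = context[len(context) - k :] if k else ""
        if len(ctx) < k or any(c not in BASE_INDEX for c in ctx):
            p = np.full(4, 0.25)
        else:
            idx = 0
            for c in ctx:
                idx = idx * 4 + BASE_INDEX[c]
            p = self.probs[idx]
        return BASES[rng.choice(4, p=p / p.sum())]


@dataclass
class PWM:
    """Position weight matrix over a window placed relative to an anchor."""

    offset: int  # window start relative to anchor position
    probs: np.ndarray  # shape (width, 4), rows normalized
    required: dict = field(default_factory=dict)  # window index -> base

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        with np.errstate(divide="ignore"):
            self.log_probs = np.log(self.probs)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score(self, enc: np.ndarray, anchor: int) -> float:
        """Log score of the window anchored at ``anchor``; out-of-bounds
        positions are skipped, but a required base that is out of bounds or
        mismatched yields -inf."""
        total = 0.0
        for w in range(self.width):
            p = anchor + self.offset + w
            if p < 0 or p >= len(enc):
                if w in self.required:
                    return NEG_INF
                continue
            b = enc[p]
            if w in self.required:
                if b != BASE_INDEX[self.required[w]]:
                    return NEG_INF
                continue  # hard-consensus bases carry probability 1
            if b < 0:
                total += LOG_QUARTER
            else:
                total += float(self.log_probs[w, b])
        return total

    def sample(self, rng: np.random.Generator) -> str:
        out = []
        for w in range(self.width):
            if w in self.required:
                out.append(self.required[w])
            else:
                p = self.probs[w]
                out.append(BASES[rng.choice(4, p=p / p.sum())])
        return "".join(out)


@dataclass
class DurationModel:
    """Explicit segment-length distribution.

    ``hist`` kind: empirical histogram over [min_len, min_len + len(probs));
    an optional geometric tail of mass ``tail_mass`` extends beyond the
    histogram with per-step decay ``tail_decay``.  ``geom`` kind: geometric
    with hard minimum (support [min_len, inf)).
    """

    kind: str  # "hist" or "geom"
    min_len: int
    probs: np.ndarray | None = None
    geom_p: float | None = None
    tail_mass: float = 0.0
    tail_decay: float = 0.99

    def __post_init__(self) -> None:
        if self.kind not in ("hist", "geom"):
            raise ValueError(f"unknown duration kind {self.kind!r}")
        if self.kind == "hist":
            self.probs = np.asarray(self.probs, dtype=float)
            s = self.probs.sum()
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                self.probs = self.probs / s

    @property
    def hist_max(self) -> int | None:
        if self.kind == "hist":
            return self.min_len + len(self.probs) - 1
        return None

    def logp(self, d: int) -> float:
        if d < self.min_len:
            return NEG_INF
        if self.kind == "geom":
            return math.log(self.geom_p) + (d - self.min_len) * math.log1p(-self.geom_p)
        hi = self.hist_max
        if d <= hi:
            p = (1.0 - self.tail_mass) * float(self.probs[d - self.min_len])
            return math.log(p) if p > 0 else NEG_INF
        if self.tail_mass > 0:
            return (
                math.log(self.tail_mass)
                + math.log(1 - self.tail_decay)
                + (d - hi - 1) * math.log(self.tail_decay)
            )
        return NEG_INF

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "geom":
            return self.min_len + int(rng.geometric(self.geom_p)) - 1
        if self.tail_mass > 0 and rng.random() < self.tail_mass:
            return self.hist_max + int(rng.geometric(1 - self.tail_decay))
        return self.min_len + int(rng.choice(len(self.probs), p=self.probs))


# ---------------------------------------------------------------------------
# the model


@dataclass
class GhmmSpec:
    """Full generative gene model: topology, durations, signals, content."""

    transitions: dict  # state -> {state: prob}; rows sum to 1
    durations: dict  # state -> DurationModel (N, I, Einit, Eint, Eterm, Esngl)
    donor_pwm: PWM
    acceptor_pwm: PWM
    start_pwm: PWM
    stop_probs: dict  # codon -> prob over the three stop codons
    coding: list  # three MarkovChain, one per codon position
    noncoding: MarkovChain = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def min_intron(self) -> int:
        if INTRON not in self.durations:
            return 20
        return self.durations[INTRON].min_len

    @property
    def order(self) -> int:
        return self.noncoding.order

    def states(self) -> tuple:
        out = {N}
        for s, row in self.transitions.items():
            out.add(s)
            out.update(row)
        return tuple(sorted(out))

    def validate(self) -> None:
        for state, row in self.transitions.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"transition row for {state} sums to {s}, not 1")
        if INTRON in self.durations and self.durations[INTRON].min_len < 20:
            raise ValueError("minimum intron length must be >= 20")
        s = sum(self.stop_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"stop-codon probabilities sum to {s}, not 1")

    def allowed_next(self, state: str) -> dict:
        return self.transitions.get(state, {})

    def log_trans(self, a: str, b: str) -> float:
        row = self.transitions.get(a)
        if row is None or b not in row:
            raise ValueError(f"illegal state adjacency {a} -> {b}")
        p = row[b]
        return math.log(p) if p > 0 else NEG_INF

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        buf = _io.StringIO()
        w = buf.write
        w("# isoscan GHMM spec v1\n")
        w(f"order\t{self.order}\n")
        w(f"pseudocount\t{self.pseudocount!r}\n")
        w("[transitions]\n")
        for a in sorted(self.transitions):
            for b in sorted(self.transitions[a]):
                w(f"{a}\t{b}\t{self.transitions[a][b]!r}\n")
        w("[durations]\n")
        for s in sorted(self.durations):
            d = self.durations[s]
            if d.kind == "geom":
                w(f"{s}\tgeom\t{d.min_len}\t{d.geom_p!r}\n")
            else:
                probs = ",".join(repr(float(p)) for p in d.probs)
                w(f"{s}\thist\t{d.min_len}\t{d.tail_mass!r}\t{d.tail_decay!r}\t{probs}\n")
        for name, pwm in (
            ("donor", self.donor_pwm),
            ("acceptor", self.acceptor_pwm),
            ("start", self.start_pwm),
        ):
            w(f"[pwm {name}]\n")
            req = ";".join(f"{k}:{v}" for k, v in sorted(pwm.required.items()))
            w(f"offset\t{pwm.offset}\trequired\t{req}\n")
            for row in pwm.probs:
                w(",".join(repr(float(p)) for p in row) + "\n")
        w("[stop]\n")
        for codon in STOP_CODONS:
            w(f"{codon}\t{self.stop_probs[codon]!r}\n")
        for i, chain in enumerate(self.coding):
            w(f"[coding {i}]\n")
            for row in chain.probs:
                w(",".join(repr(float(p)) for p in row) + "\n")
        w("[noncoding]\n")
        for row in self.noncoding.probs:
            w(",".join(repr(float(p)) for p in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "GhmmSpec":
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        order = 0
        pseudocount = 1.0
        transitions: dict = {}
        durations: dict = {}
        pwms: dict = {}
        stop_probs: dict = {}
        coding_rows: dict = {0: [], 1: [], 2: []}
        noncoding_rows: list = []
        section = None
        pwm_meta: dict = {}
        i = 0
        while i < len(lines):
            ln = lines[i]
            if ln.startswith("["):
                section = ln.strip("[]")
                i += 1
                continue
            parts = ln.split("\t")
            if section is None:
                if parts[0] == "order":
                    order = int(parts[1])
                elif parts[0] == "pseudocount":
                    pseudocount = float(parts[1])
            elif section == "transitions":
                transitions.setdefault(parts[0], {})[parts[1]] = float(parts[2])
            elif section == "durations":
                state, kind = parts[0], parts[1]
                if kind == "geom":
                    durations[state] = DurationModel(
                        "geom", int(parts[2]), geom_p=float(parts[3])
                    )
                else:
                    probs = np.array([float(x) for x in parts[5].split(",")])
                    durations[state] = DurationModel(
                        "hist",
                        int(parts[2]),
                        probs=probs,
                        tail_mass=float(parts[3]),
                        tail_decay=float(parts[4]),
                    )
            elif section.startswith("pwm "):
                name = section.split()[1]
                if parts[0] == "offset":
                    req = {}
                    if len(parts) > 3 and parts[3]:
                        for item in parts[3].split(";"):
                            k, v = item.split(":")
                            req[int(k)] = v
                    pwm_meta[name] = (int(parts[1]), req)
                    pwms.setdefault(name, [])
                else:
                    pwms[name].append([float(x) for x in ln.split(",")])
            elif section == "stop":
                stop_probs[parts[0]] = float(parts[1])
            elif section.startswith("coding"):
                idx = int(section.split()[1])
                coding_rows[idx].append([float(x) for x in ln.split(",")])
            elif section == "noncoding":
                noncoding_rows.append([float(x) for x in ln.split(",")])
            i += 1
        built_pwms = {
            name: PWM(pwm_meta[name][0], np.array(rows), required=pwm_meta[name][1])
            for name, rows in pwms.items()
        }
        return cls(
            transitions=transitions,
            durations=durations,
            donor_pwm=built_pwms["donor"],
            acceptor_pwm=built_pwms["acceptor"],
            start_pwm=built_pwms["start"],
            stop_probs=stop_probs,
            coding=[MarkovChain(order, np.array(coding_rows[i])) for i in range(3)],
            noncoding=MarkovChain(order, np.array(noncoding_rows)),
            pseudocount=pseudocount,
        )


# ---------------------------------------------------------------------------
# path scoring


@dataclass(frozen=True)
class Segment:
    state: str
    length: int


def _is_stop(s: str) -> bool:
    return s in STOP_CODONS


def _coding_logp(
    spec: GhmmSpec, enc: np.ndarray, start: int, end: int, phase: int
) -> float:
    """Content-chain score of coding bases [start, end); base at p has codon
    position (phase + p - start) mod 3; first ``order`` bases of the segment
    are uniform."""
    total = 0.0
    k = spec.order
    for p in range(start, end):
        if p - start < k:
            total += LOG_QUARTER
            continue
        b = enc[p]
        if b < 0:
            total += LOG_QUARTER
            continue
        chain = spec.coding[(phase + p - start) % 3]
        ctx = chain.context_index(enc, p)
        total += LOG_QUARTER if ctx < 0 else float(chain.log_probs[ctx, b])
    return total


def log_score_path(
    spec: GhmmSpec, sequence: str, path: Sequence[Segment | tuple]
) -> float:
    """Log-probability of a complete state/duration segmentation.

    Raises ``ValueError`` for caller bugs (segments not tiling the sequence,
    adjacency not permitted by the topology, first segment not intergenic,
    terminal segment not a legal end state).  Returns ``-inf`` for paths that
    are topologically legal but contain a forbidden component: bad ORF
    (missing ATG/stop, internal in-frame stop including split codons),
    missing GT/AG, unsupported duration (e.g. intron below the minimum), or a
    zero-probability transition.
    """
    segs = [s if isinstance(s, Segment) else Segment(*s) for s in path]
    if sum(s.length for s in segs) != len(sequence):
        raise ValueError("path does not tile the sequence")
    if not segs or segs[0].state != N:
        raise ValueError("paths must start in the intergenic state")
    if segs[-1].state not in TERMINAL_STATES:
        raise ValueError(f"path may not end in state {segs[-1].state}")

    enc = encode(sequence)
    seq = sequence.upper()
    total = 0.0
    pos = 0
    prev: str | None = None
    phase = 0
    dangling = ""  # split-codon bases carried across the current intron
    for seg in segs:
        st, d = seg.state, seg.length
        if d < 1:
            raise ValueError("segment length must be >= 1")
        if prev is not None:
            total += spec.log_trans(prev, st)
        if st in spec.durations:
            total += spec.durations[st].logp(d)
        end = pos + d
        bases = seq[pos:end]

        if st == N:
            total += spec.noncoding.logp_segment(enc, pos, end)
        elif st == INTRON:
            if d < spec.min_intron:
                return NEG_INF
            if not (bases.startswith("GT") and bases.endswith("AG")):
                return NEG_INF
            total += spec.noncoding.logp_segment(
                enc, pos + DONOR_WIDTH, end - ACCEPTOR_WIDTH
            )
            total += spec.donor_pwm.score(enc, pos)
            total += spec.acceptor_pwm.score(enc, end)
        elif st in EXON_STATES:
            if d < MIN_EXON:
                return NEG_INF
            code_start = pos
            if st in (EINIT, ESNGL):
                if not bases.startswith("ATG"):
                    return NEG_INF
                total += spec.start_pwm.score(enc, pos)
                phase, dangling = 0, ""
                code_start = pos + 3
            s = dangling + bases
            terminal = st in (ETERM, ESNGL)
            if terminal:
                if len(s) % 3 != 0:
                    return NEG_INF
                last = s[-3:]
                if not _is_stop(last):
                    return NEG_INF
                total += math.log(spec.stop_probs[last])
            n_full = len(s) // 3
            limit = n_full - 1 if terminal else n_full
            for c in range(limit):
                if _is_stop(s[3 * c : 3 * c + 3]):
                    return NEG_INF
            code_end = end - 3 if terminal else end
            code_phase = 0 if st in (EINIT, ESNGL) else phase
            total += _coding_logp(spec, enc, code_start, code_end, code_phase)
            new_phase = (phase + d) % 3
            dangling = s[len(s) - new_phase :] if new_phase else ""
            phase = new_phase
        else:
            raise ValueError(f"unknown state {st!r}")
        pos = end
        prev = st
    if prev in (EINIT, EINT, INTRON):
        raise ValueError("path ends inside a gene")  # unreachable with check above
    if total == NEG_INF or math.isnan(total):
        return NEG_INF
    return total


# ---------------------------------------------------------------------------
# sampling


def _sample_noncoding(spec: GhmmSpec, rng: np.random.Generator, length: int) -> str:
    out: list[str] = []
    ctx = ""
    k = spec.order
    for _ in range(length):
        b = spec.noncoding.sample_base(rng, ctx)
        out.append(b)
        ctx = (ctx + b)[-k:] if k else ""
    return "".join(out)


def _sample_cds(spec: GhmmSpec, rng: np.random.Generator, length: int) -> str:
    """Sample a complete ORF of the given length (multiple of 3, >= 6)."""
    if length % 3 != 0 or length < 6:
        raise ValueError("CDS length must be a multiple of 3 and >= 6")
    out = list("ATG")
    while len(out) < length - 3:
        codon_start = len(out)
        for _ in range(3):
            pos = len(out)
            chain = spec.coding[pos % 3]
            out.append(chain.sample_base(rng, "".join(out)))
        if _is_stop("".join(out[codon_start:])):
            del out[codon_start:]  # reject interior stop codons
    stops, probs = zip(*sorted(spec.stop_probs.items()))
    out.append(stops[int(rng.choice(len(stops), p=np.array(probs) / sum(probs)))])
    return "".join(out)


def _sample_gene_structure(
    spec: GhmmSpec, rng: np.random.Generator
) -> list[Segment]:
    """Sample the exon/intron layout of one gene (no sequence yet)."""
    row = spec.transitions[N]
    states = sorted(row)
    probs = np.array([row[s] for s in states])
    first = states[int(rng.choice(len(states), p=probs / probs.sum()))]
    if first == ESNGL:
        for _ in range(1000):
            d = spec.durations[ESNGL].sample(rng)
            if d % 3 == 0 and d >= 6:
                return [Segment(ESNGL, d)]
        raise RuntimeError("could not sample a single-exon duration (mod 3)")
    segs = [Segment(EINIT, spec.durations[EINIT].sample(rng))]
    coding = segs[0].length
    irow = spec.transitions[INTRON]
    while True:
        segs.append(Segment(INTRON, spec.durations[INTRON].sample(rng)))
        nxt_states = sorted(irow)
        nxt_probs = np.array([irow[s] for s in nxt_states])
        nxt = nxt_states[int(rng.choice(len(nxt_states), p=nxt_probs / nxt_probs.sum()))]
        if nxt == EINT:
            d = spec.durations[EINT].sample(rng)
            segs.append(Segment(EINT, d))
            coding += d
        else:
            for _ in range(1000):
                d = spec.durations[ETERM].sample(rng)
                if (coding + d) % 3 == 0 and coding + d >= 6:
                    segs.append(Segment(ETERM, d))
                    return segs
            raise RuntimeError("could not sample a terminal-exon duration (mod 3)")


def sample_with_paths(
    spec: GhmmSpec,
    target_length: int,
    seed: int,
    sequence_id: str = "chr_sim",
    gene_prefix: str = "g",
) -> tuple[str, list[Transcript], list[Segment]]:
    """Sample a genome of approximately ``target_length`` nt together with the
    true gene structures and the generating state path.

    The sequence always begins and ends in intergenic state; a gene whose
    sampled layout would overrun the target is dropped and the trailing
    intergenic segment is extended to close the sequence exactly at
    ``target_length``.  Deterministic under a fixed seed.
    """
    if target_length < 40:
        raise ValueError("target_length too small to hold intergenic padding")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    path: list[Segment] = []
    transcripts: list[Transcript] = []
    pos = 0
    gene_no = 0
    while True:
        gap = spec.durations[N].sample(rng)
        gene = _sample_gene_structure(spec, rng)
        span = sum(s.length for s in gene)
        # leave room for a closing intergenic segment
        if pos + gap + span + 1 > target_length:
            tail = target_length - pos
            if path and path[-1].state == N:
                path[-1] = Segment(N, path[-1].length + tail)
            else:
                path.append(Segment(N, tail))
            parts.append(_sample_noncoding(spec, rng, tail))
            break
        parts.append(_sample_noncoding(spec, rng, gap))
        path.append(Segment(N, gap))
        pos += gap
        # emit the gene: CDS sampled as one ORF, then split by introns
        cds_len = sum(s.length for s in gene if s.state in EXON_STATES)
        cds = _sample_cds(spec, rng, cds_len)
        exons: list[GenomicInterval] = []
        cds_used = 0
        for seg in gene:
            if seg.state in EXON_STATES:
                parts.append(cds[cds_used : cds_used + seg.length])
                exons.append(
                    GenomicInterval(sequence_id, pos, pos + seg.length, "+")
                )
                cds_used += seg.length
            else:
                interior = _sample_noncoding(
                    spec, rng, seg.length - DONOR_WIDTH - ACCEPTOR_WIDTH
                )
                parts.append(
                    spec.donor_pwm.sample(rng) + interior + spec.acceptor_pwm.sample(rng)
                )
            path.append(seg)
            pos += seg.length
        gene_no += 1
        tid = f"{gene_prefix}{gene_no}.t1"
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=f"{gene_prefix}{gene_no}",
                exons=tuple(exons),
                cds_start=exons[0].start,
                cds_end=exons[-1].end,
                source_tag="ALTSCAN",
            )
        )
    return "".join(parts), transcripts, path


def sample(
    spec: GhmmSpec, target_length: int, seed: int, sequence_id: str = "chr_sim"
) -> tuple[str, list[Transcript]]:
    seq, transcripts, _ = sample_with_paths(spec, target_length, seed, sequence_id)
    return seq, transcripts


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingCorpus:
    """Sequences plus complete-ORF transcript annotations."""

    sequences: Mapping[str, str]
    transcripts: Sequence[Transcript]


@dataclass
class TrainConfig:
    order: int = 2
    pseudocount: float = 1.0
    min_intron: int = 20


def _count_chain(
    counts: np.ndarray, enc: np.ndarray, order: int, start: int, end: int
) -> None:
    for p in range(start + order, end):
        b = enc[p]
        if b < 0:
            continue
        idx = 0
        ok = True
        for q in range(p - order, p):
            if enc[q] < 0:
                ok = False
                break
            idx = idx * 4 + int(enc[q])
        if ok:
            counts[idx, b] += 1


def _spliced_cds(genome: Mapping[str, str], t: Transcript) -> str:
    seq = genome[t.sequence_id]
    s = "".join(seq[e.start : e.end] for e in t.cds_exons())
    return revcomp(s) if t.strand == "-" else s.upper()


def _check_orf(cds: str, tid: str) -> None:
    if len(cds) % 3 != 0 or len(cds) < 6:
        raise ValueError(f"{tid}: CDS length {len(cds)} is not a complete ORF")
    if not cds.startswith("ATG"):
        raise ValueError(f"{tid}: CDS does not start with ATG")
    if not _is_stop(cds[-3:]):
        raise ValueError(f"{tid}: CDS does not end with a stop codon")
    for c in range(0, len(cds) - 3, 3):
        if _is_stop(cds[c : c + 3]):
            raise ValueError(f"{tid}: internal in-frame stop codon")


def _hist_duration(lengths: list[int], lo: int, pseudocount: float) -> DurationModel:
    usable = [d for d in lengths if d >= lo]
    if len(usable) < len(lengths):
        logger.info("duration training: dropped %d sub-minimum exon lengths", len(lengths) - len(usable))
    hi = max(usable)
    counts = np.full(hi - lo + 1, pseudocount, dtype=float)
    for d in usable:
        counts[d - lo] += 1
    return DurationModel("hist", lo, probs=counts / counts.sum())


def train(corpus: TrainingCorpus, config: TrainConfig | None = None) -> GhmmSpec:
    """Maximum-likelihood estimation with additive pseudocounts.

    Reverse-strand transcripts are mirrored onto the forward strand of the
    reverse complement before counting.  Signal windows that extend beyond
    the sequence bounds are skipped with a logged count.
    """
    config = config or TrainConfig()
    if not corpus.transcripts:
        raise ValueError("training corpus is empty")
    k, pc = config.order, config.pseudocount

    coding_counts = [np.full((4**k, 4), pc) for _ in range(3)]
    noncoding_counts = np.full((4**k, 4), pc)
    donor_counts = np.full((DONOR_WIDTH, 4), pc)
    acceptor_counts = np.full((ACCEPTOR_WIDTH, 4), pc)
    start_counts = np.full((START_WIDTH, 4), pc)
    stop_counts = {c: pc for c in STOP_CODONS}
    exon_lengths: dict = {EINIT: [], EINT: [], ETERM: [], ESNGL: []}
    intron_lengths: list[int] = []
    intergenic_lengths: list[int] = []
    n_single = n_multi = 0
    n_eint = n_eterm = 0
    skipped_windows = 0

    # genes grouped per (sequence, strand), strand-mirrored to forward
    by_seq: dict = {}
    for t in corpus.transcripts:
        by_seq.setdefault((t.sequence_id, t.strand), []).append(t)

    for (seq_id, strand), ts in sorted(by_seq.items()):
        raw = corpus.sequences[seq_id].upper()
        seq = revcomp(raw) if strand == "-" else raw
        L = len(seq)

        def fwd(iv: GenomicInterval) -> tuple[int, int]:
            if strand == "-":
                return L - iv.end, L - iv.start
            return iv.start, iv.end

        enc = encode(seq)
        genes = sorted(
            ((min(fwd(e)[0] for e in t.cds_exons()), t) for t in ts),
            key=lambda x: x[0],
        )
        prev_end = 0
        for _, t in genes:
            cds = _spliced_cds(corpus.sequences, t)
            _check_orf(cds, t.transcript_id)
            exons = sorted(fwd(e) for e in t.cds_exons())
            gstart, gend = exons[0][0], exons[-1][1]
            if gstart > prev_end:
                intergenic_lengths.append(gstart - prev_end)
                _count_chain(noncoding_counts, enc, k, prev_end, gstart)
            prev_end = max(prev_end, gend)
            # content: coding chain by codon position over the spliced CDS
            enc_cds = encode(cds)
            for p in range(k, len(cds) - 3):
                b = enc_cds[p]
                if b < 0:
                    continue
                idx = 0
                ok = all(enc_cds[q] >= 0 for q in range(p - k, p))
                if not ok:
                    continue
                for q in range(p - k, p):
                    idx = idx * 4 + int(enc_cds[q])
                coding_counts[p % 3][idx, b] += 1
            stop_counts[cds[-3:]] += 1
            # durations / transitions
            if len(exons) == 1:
                n_single += 1
                exon_lengths[ESNGL].append(exons[0][1] - exons[0][0])
            else:
                n_multi += 1
                exon_lengths[EINIT].append(exons[0][1] - exons[0][0])
                exon_lengths[ETERM].append(exons[-1][1] - exons[-1][0])
                for s, e in exons[1:-1]:
                    exon_lengths[EINT].append(e - s)
                n_eint += max(0, len(exons) - 2)
                n_eterm += 1
                for (s1, e1), (s2, _) in zip(exons, exons[1:]):
                    d = s2 - e1
                    intron_lengths.append(d)
                    _count_chain(
                        noncoding_counts, enc, k, e1 + DONOR_WIDTH, s2 - ACCEPTOR_WIDTH
                    )
                    # donor window anchored at first intron base
                    if e1 + DONOR_OFFSET >= 0 and e1 + DONOR_OFFSET + DONOR_WIDTH <= L:
                        for w in range(DONOR_WIDTH):
                            b = enc[e1 + DONOR_OFFSET + w]
                            if b >= 0:
                                donor_counts[w, b] += 1
                    else:
                        skipped_windows += 1
                    if s2 + ACCEPTOR_OFFSET >= 0 and s2 + ACCEPTOR_OFFSET + ACCEPTOR_WIDTH <= L:
                        for w in range(ACCEPTOR_WIDTH):
                            b = enc[s2 + ACCEPTOR_OFFSET + w]
                            if b >= 0:
                                acceptor_counts[w, b] += 1
                    else:
                        skipped_windows += 1
            if gstart + START_OFFSET >= 0 and gstart + START_OFFSET + START_WIDTH <= L:
                for w in range(START_WIDTH):
                    b = enc[gstart + START_OFFSET + w]
                    if b >= 0:
                        start_counts[w, b] += 1
            else:
                skipped_windows += 1
        if prev_end < L:
            intergenic_lengths.append(L - prev_end)
            _count_chain(noncoding_counts, enc, k, prev_end, L)

    if skipped_windows:
        logger.info("train: skipped %d out-of-bounds signal windows", skipped_windows)

    def norm(a: np.ndarray) -> np.ndarray:
        return a / a.sum(axis=1, keepdims=True)

    n_genes = n_single + n_multi
    transitions = {
        N: {
            ESNGL: (n_single + pc) / (n_genes + 2 * pc),
            EINIT: (n_multi + pc) / (n_genes + 2 * pc),
        },
        EINIT: {INTRON: 1.0},
        EINT: {INTRON: 1.0},
        INTRON: {
            EINT: (n_eint + pc) / (n_eint + n_eterm + 2 * pc),
            ETERM: (n_eterm + pc) / (n_eint + n_eterm + 2 * pc),
        },
        ETERM: {N: 1.0},
        ESNGL: {N: 1.0},
    }

    def geom_model(lengths: list[int], minimum: int) -> DurationModel:
        mean = float(np.mean(lengths)) if lengths else minimum + 50.0
        p = 1.0 / max(mean - minimum + 1.0, 1.000001)
        return DurationModel("geom", minimum, geom_p=p)

    durations = {
        N: geom_model(intergenic_lengths, 1),
        INTRON: geom_model(intron_lengths, config.min_intron),
    }
    for st in (EINIT, EINT, ETERM, ESNGL):
        if exon_lengths[st]:
            durations[st] = _hist_duration(exon_lengths[st], MIN_EXON, pc)
        else:
            durations[st] = DurationModel(
                "hist", MIN_EXON, probs=np.full(298, 1 / 298.0)
            )

    stop_total = sum(stop_counts.values())
    return GhmmSpec(
        transitions=transitions,
        durations=durations,
        donor_pwm=PWM(DONOR_OFFSET, norm(donor_counts), required={0: "G", 1: "T"}),
        acceptor_pwm=PWM(
            ACCEPTOR_OFFSET, norm(acceptor_counts), required={11: "A", 12: "G"}
        ),
        start_pwm=PWM(START_OFFSET, norm(start_counts), required={0: "A", 1: "T", 2: "G"}),
        stop_probs={c: stop_counts[c] / stop_total for c in STOP_CODONS},
        coding=[MarkovChain(k, norm(c)) for c in coding_counts],
        noncoding=MarkovChain(k, norm(noncoding_counts)),
        pseudocount=pc,
    )
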