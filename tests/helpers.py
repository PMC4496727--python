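"""Brute-force oracles shared by the test suite.

The path enumerator is deliberately independent of the decoder: it tries
every segmentation compatible with the model topology and duration supports,
scores each candidate with :func:`isoscan.ghmm.log_score_path` and keeps the
finite ones.  Only cheap structural prunes (required consensus bases,
divisibility) are applied before scoring, and each of them mirrors a hard
constraint of the scoring function itself.
"""

from __future__ import annotations

import math

from isoscan.ghmm import (
    EINIT,
    EINT,
    ESNGL,
    ETERM,
    INTRON,
    N,
    STOP_CODONS,
    TERMINAL_STATES,
    GhmmSpec,
    Segment,
    log_score_path,
)

_STATE_RANK = {N: 0, ESNGL: 1, EINIT: 2, INTRON: 3, EINT: 4, ETERM: 5}


def _has_frame_stop(seq: str, start: int, end: int) -> bool:
    """Any full codon stop in [start, end) with codons anchored at start."""
    for p in range(start, end - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return True
    return False


def _quick_legal(seq: str, state: str, pos: int, d: int, min_intron: int) -> bool:
    end = pos + d
    if state == ESNGL:
        return (
            d >= 6
            and d % 3 == 0
            and seq[pos : pos + 3] == "ATG"
            and seq[end - 3 : end] in STOP_CODONS
            and not _has_frame_stop(seq, pos, end - 3)
        )
    if state == EINIT:
        return d >= 3 and seq[pos : pos + 3] == "ATG"
    if state == INTRON:
        return d >= min_intron and seq[pos : pos + 2] == "GT" and seq[end - 2 : end] == "AG"
    if state == EINT:
        return d >= 3
    if state == ETERM:
        return d >= 3 and seq[end - 3 : end] in STOP_CODONS
    return True  # N


def enumerate_paths(spec: GhmmSpec, seq: str) -> list[tuple[float, tuple]]:
    """All legal segmentations, scored, sorted like the decoder sorts.

    Returns (score, path) descending by score, ties broken lexicographically
    by the (state-rank, segment-start) encoding.
    """
    L = len(seq)
    durations = spec.durations
    results: list[tuple[float, tuple]] = []

    def support(state: str, remaining: int):
        m = durations[state]
        if m.kind == "hist":
            hi = min(m.hist_max, remaining)
        else:
            hi = remaining
        return range(max(m.min_len, 1), hi + 1)

    def rec(pos: int, prev: str | None, segs: list) -> None:
        remaining = L - pos
        if remaining == 0:
            if segs and segs[-1].state in TERMINAL_STATES:
                score = log_score_path(spec, seq, segs)
                if score != float("-inf"):
                    results.append((score, tuple(segs)))
            return
        nxt = [N] if prev is None else list(spec.transitions.get(prev, {}))
        for state in nxt:
            if state not in durations:
                continue
            for d in support(state, remaining):
                if not _quick_legal(seq, state, pos, d, spec.min_intron):
                    continue
                segs.append(Segment(state, d))
                rec(pos + d, state, segs)
                segs.pop()

    rec(0, None, [])

    def encoding(path: tuple) -> tuple:
        out, pos = [], 0
        for seg in path:
            out.append((_STATE_RANK[seg.state], pos))
            pos += seg.length
        return tuple(out)

    results.sort(key=lambda item: (-item[0], encoding(item[1])))
    return results


def assert_same_ranking(decoded, enumerated, k: int, tol: float = 1e-9) -> None:
    """Decoded top-k equals the enumeration top-k in set and order.

    Exactly tied scores may be computed in different float orders by the two
    routes, so ordering is compared group-wise: paths whose scores agree
    within ``tol`` form one rank group and must contain the same paths.
    """
    expect = enumerated[:k]
    assert len(decoded) == min(k, len(enumerated)), (
        f"decoder returned {len(decoded)} paths, enumeration has {len(enumerated)}"
    )
    for sp, (score, _) in zip(decoded, expect):
        assert math.isclose(sp.log_score, score, abs_tol=1e-6), (
            sp.log_score,
            score,
        )
    i = 0
    while i < len(expect):
        j = i
        while j < len(expect) and abs(expect[j][0] - expect[i][0]) <= tol:
            j += 1
        got = {d.path for d in decoded[i:j]}
        want = {p for _, p in expect[i:j]}
        assert got == want, f"rank group {i}:{j} differs:\n{got}\n{want}"
        i = j


def random_toy_sequence(rng, length: int, kind: str) -> str:
    """Random <=30 nt sequences, some with planted gene-like structure.

    The biased kinds oversample start/stop/splice motifs so that short
    sequences carry several competing legal segmentations.
    """
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    def motif_rich(n):
        # A/T/G-heavy composition breeds ATG and stop codons in all frames
        p = [0.36, 0.08, 0.26, 0.30]
        return "".join(bases[i] for i in rng.choice(4, size=n, p=p))

    if kind == "random":
        return rand(length)
    if kind == "single_exon":
        # several in-frame ATGs sharing downstream stops
        n1 = int(rng.integers(1, 4))
        body = "ATGATG" + motif_rich(3 * int(rng.integers(1, 4))) + (
            "TAA",
            "TAG",
            "TGA",
        )[rng.integers(0, 3)]
        n2 = max(0, length - n1 - len(body))
        return (motif_rich(n1) + body + motif_rich(n2))[:length]
    # two-exon gene with a minimum-length intron offering alternative
    # donors (GTAGT), acceptors (AGAGAG) and start codons (ATGATG)
    n1 = int(rng.integers(1, 3))
    intron = "GTAGT" + motif_rich(9) + "AGAGAG"
    body = "ATGATG" + intron
    tail = ("TAA", "TAG", "TGA")[rng.integers(0, 3)] + "TAATGA"
    s = motif_rich(n1) + body + tail
    return (s + motif_rich(max(0, length - len(s))))[:length]
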