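"""Alternative-splicing event classification between isoforms of a gene.

Events are called pairwise between transcripts of the same gene, restricted
to coding regions (UTR-only differences are ignored), then deduplicated by
(gene, category, signature) where the signature is the set of distinguishing
splice-site (or CDS-boundary) genomic offsets.  Seven categories:

* ``exon_skipping`` — an internal CDS exon of one isoform absent from the
  other, with both flanking junctions fused into one junction there;
* ``alt_donor`` / ``alt_acceptor`` — two junctions sharing one splice site
  but not the other, with overlapping exons on the differing side
  (strand-aware: the donor is the 5' site of the intron);
* ``intron_retention`` — an intron of one isoform fully contained inside a
  CDS exon of the other;
* ``mutually_exclusive_exons`` — two non-overlapping internal exons that
  replace each other between shared flanking junctions;
* ``alt_translation_start`` / ``alt_translation_stop`` — differing CDS
  boundary positions (transcriptional rather than splicing variation, but
  counted among the categories).

Event sizes are measured by the number of splice sites in the signature,
so per-category tallies can be compared across datasets of different
granularity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import Transcript

CATEGORIES = (
    "exon_skipping",
    "alt_donor",
    "alt_acceptor",
    "intron_retention",
    "mutually_exclusive_exons",
    "alt_translation_start",
    "alt_translation_stop",
)


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    category: str
    signature: frozenset  # distinguishing genomic offsets
    pair: tuple = ()  # witnessing transcript ids (not part of identity)

    @property
    def n_sites(self) -> int:
        return len(self.signature)

    def identity(self) -> tuple:
        return (self.gene_id, self.category, self.signature)


def _cds_layout(t: Transcript):
    exons = [(e.start, e.end) for e in t.cds_exons()]
    juncs = {(a[1], b[0]) for a, b in zip(exons, exons[1:])}
    return exons, juncs


def classify_pair(t1: Transcript, t2: Transcript) -> list[ASEvent]:
    """All category instances distinguishing the CDS structures of a pair.

    The returned (category, signature) set is symmetric in the argument
    order.  Raises for transcripts on different strands.
    """
    if t1.strand != t2.strand:
        raise ValueError("cannot classify transcripts on different strands")
    gene = t1.gene_id
    strand = t1.strand
    ex1, j1 = _cds_layout(t1)
    ex2, j2 = _cds_layout(t2)
    pair = (t1.transcript_id, t2.transcript_id)
    events: dict = {}

    def add(category: str, sites: Iterable[int]) -> None:
        ev = ASEvent(gene, category, frozenset(sites), pair)
        events[ev.identity()] = ev

    # alternative translation boundaries (5'/3' assignment is strand-aware)
    s1, e1 = ex1[0][0], ex1[-1][1]
    s2, e2 = ex2[0][0], ex2[-1][1]
    left_differs, right_differs = s1 != s2, e1 != e2
    if left_differs:
        add("alt_translation_start" if strand == "+" else "alt_translation_stop", {s1, s2})
    if right_differs:
        add("alt_translation_stop" if strand == "+" else "alt_translation_start", {e1, e2})

    for (ea, ja), (eb, jb) in (((ex1, j1), (ex2, j2)), ((ex2, j2), (ex1, j1))):
        # exon skipping: internal exon of A absent from B, flanks fused in B
        for i in range(1, len(ea) - 1):
            s, e = ea[i]
            prev_end, next_start = ea[i - 1][1], ea[i + 1][0]
            if (
                (prev_end, s) in ja
                and (e, next_start) in ja
                and (prev_end, next_start) in jb
                and not any(bs < e and s < be for bs, be in eb)
            ):
                add("exon_skipping", {s, e})
        # intron retention: intron of A strictly inside an exon of B
        for (x, y) in ja:
            if any(bs < x and y < be for bs, be in eb):
                add("intron_retention", {x, y})
        # alt 5'/3' splice sites: junctions sharing one end, overlapping exons
        # on the differing side
        for (x1, y1) in ja:
            for (x2, y2) in jb:
                if x1 == x2 and y1 != y2:
                    down_a = next(((s, e) for s, e in ea if s == y1), None)
                    down_b = next(((s, e) for s, e in eb if s == y2), None)
                    if down_a and down_b and down_a[0] < down_b[1] and down_b[0] < down_a[1]:
                        add("alt_acceptor" if strand == "+" else "alt_donor", {y1, y2})
                elif y1 == y2 and x1 != x2:
                    up_a = next(((s, e) for s, e in ea if e == x1), None)
                    up_b = next(((s, e) for s, e in eb if e == x2), None)
                    if up_a and up_b and up_a[0] < up_b[1] and up_b[0] < up_a[1]:
                        add("alt_donor" if strand == "+" else "alt_acceptor", {x1, x2})
        # mutually exclusive exons: internal exons replacing each other
        # between shared flanking junctions, no skipping junction present
        for i in range(1, len(ea) - 1):
            s1_, e1_ = ea[i]
            pa, na = ea[i - 1][1], ea[i + 1][0]
            for k in range(1, len(eb) - 1):
                s2_, e2_ = eb[k]
                pb, nb = eb[k - 1][1], eb[k + 1][0]
                if (
                    pa == pb
                    and na == nb
                    and e1_ <= s2_  # disjoint (orientation handled by the swap)
                    and (pa, na) not in ja | jb
                    and not any(bs < e1_ and s1_ < be for bs, be in eb)
                    and not any(bs < e2_ and s2_ < be for bs, be in ea)
                ):
                    add("mutually_exclusive_exons", {s1_, e1_, s2_, e2_})
    return sorted(events.values(), key=lambda ev: (ev.category, sorted(ev.signature)))


def count_events(
    transcripts_by_gene: Mapping[str, Sequence[Transcript]]
) -> dict[str, dict]:
    """Deduplicated event and splice-site tallies per category.

    Classifies every transcript pair within each gene, deduplicates by
    (gene, category, signature) and reports, per category, the number of
    distinct events and the total number of splice sites involved.
    """
    seen: dict = {}
    for gene, ts in transcripts_by_gene.items():
        ts = list(ts)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                for ev in classify_pair(ts[i], ts[j]):
                    seen.setdefault(ev.identity(), ev)
    out = {c: {"events": 0, "sites": 0} for c in CATEGORIES}
    for ev in seen.values():
        out[ev.category]["events"] += 1
        out[ev.category]["sites"] += ev.n_sites
    return out


def transcripts_per_gene_stats(
    transcripts_by_gene: Mapping[str, Sequence[Transcript]],
    histogram_cap: int = 20,
) -> dict:
    """Transcripts-per-gene histogram (capped at a ">cap" bucket), mean
    transcripts per gene, and the fraction of multi-exon genes carrying a
    single transcript."""
    hist: Counter = Counter()
    n_multi_genes = 0
    n_multi_single = 0
    total_transcripts = 0
    for gene, ts in transcripts_by_gene.items():
        n = len(ts)
        total_transcripts += n
        hist[min(n, histogram_cap + 1)] += 1
        if any(t.is_multi_exon() for t in ts):
            n_multi_genes += 1
            if n == 1:
                n_multi_single += 1
    n_genes = len(transcripts_by_gene)
    return {
        "histogram": dict(sorted(hist.items())),
        "mean_transcripts_per_gene": total_transcripts / n_genes if n_genes else 0.0,
        "fraction_multi_exon_single_transcript": (
            n_multi_single / n_multi_genes if n_multi_genes else 0.0
        ),
        "n_genes": n_genes,
    }
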