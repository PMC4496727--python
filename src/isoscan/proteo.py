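"""Novel-peptide and novel-protein set logic downstream of spectral search.

Peptide identifications arrive as hits against a combined database of
reference (REFSEQ-tagged) and candidate (VMC-tagged) protein sequences.
Preliminary novel peptides are those scored only against the candidate
database; candidate novel proteins need at least two unique peptides, at
least one of them novel; and a final annotation filter removes candidates
whose novel peptides all occur verbatim in external protein databases
(exact substring matching stands in for a protein-level alignment search —
conservative at tryptic-peptide length scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

REFSEQ, VMC = "REFSEQ", "VMC"


@dataclass(frozen=True)
class PeptideHit:
    """One identified peptide with its matched protein accessions per database."""

    peptide: str
    accessions: tuple  # of (db_tag, accession)
    spectral_count: int = 1

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if not self.accessions:
            raise ValueError(f"{self.peptide}: needs at least one accession")

    def dbs(self) -> set:
        return {db for db, _ in self.accessions}

    def proteins(self, db: str) -> set:
        return {acc for d, acc in self.accessions if d == db}


@dataclass
class NovelProteinCall:
    accession: str
    unique_peptides: tuple
    novel_peptides: tuple
    in_gencode: bool = False
    in_swissprot: bool = False
    covers_novel_junction: bool = False


def find_preliminary_novel(hits: Sequence[PeptideHit]) -> set[str]:
    """Peptides scored against the candidate database but not the reference.

    Database membership is pooled per peptide sequence across all hit rows.
    """
    dbs: dict[str, set] = {}
    for h in hits:
        dbs.setdefault(h.peptide, set()).update(h.dbs())
    return {pep for pep, d in dbs.items() if VMC in d and REFSEQ not in d}


def call_candidate_proteins(
    hits: Sequence[PeptideHit], novel_peptides: set[str] | None = None
) -> list[NovelProteinCall]:
    """Candidate novel proteins: >= 2 unique peptides including >= 1 novel.

    A peptide is *unique* to a candidate protein when it maps to exactly one
    candidate (VMC) accession.  Matches against the reference database make
    a peptide non-novel but do not break uniqueness — otherwise a candidate
    protein sharing most of its sequence with its reference counterpart
    could never accumulate a second unique peptide.
    """
    if novel_peptides is None:
        novel_peptides = find_preliminary_novel(hits)
    per_peptide: dict[str, set] = {}
    for h in hits:
        per_peptide.setdefault(h.peptide, set()).update(h.accessions)
    unique_by_protein: dict[str, set] = {}
    for pep, accs in per_peptide.items():
        vmc_accs = {acc for db, acc in accs if db == VMC}
        if len(vmc_accs) == 1:
            unique_by_protein.setdefault(next(iter(vmc_accs)), set()).add(pep)
    calls = []
    for acc in sorted(unique_by_protein):
        peps = unique_by_protein[acc]
        novel = peps & novel_peptides
        if len(peps) >= 2 and novel:
            calls.append(
                NovelProteinCall(
                    accession=acc,
                    unique_peptides=tuple(sorted(peps)),
                    novel_peptides=tuple(sorted(novel)),
                )
            )
    return calls


def external_annotation_filter(
    calls: Sequence[NovelProteinCall],
    gencode_proteins: Iterable[str],
    swissprot_proteins: Iterable[str],
) -> tuple[list[NovelProteinCall], dict]:
    """Drop candidates whose novel peptides are all annotated externally.

    A call counts as annotated in a database when every one of its novel
    peptides occurs as an exact substring of some protein sequence there.
    Returns the final novel calls (annotated in neither database) and the
    cross-tab counts: candidates, both, gencode_only, swissprot_only, final.
    """
    gen = list(gencode_proteins)
    swp = list(swissprot_proteins)

    def annotated(call: NovelProteinCall, db: list[str]) -> bool:
        return bool(db) and all(
            any(pep in seq for seq in db) for pep in call.novel_peptides
        )

    final = []
    n_both = n_gen = n_swp = 0
    for call in calls:
        call.in_gencode = annotated(call, gen)
        call.in_swissprot = annotated(call, swp)
        if call.in_gencode and call.in_swissprot:
            n_both += 1
        elif call.in_gencode:
            n_gen += 1
        elif call.in_swissprot:
            n_swp += 1
        else:
            final.append(call)
    counts = {
        "candidates": len(calls),
        "both": n_both,
        "gencode_only": n_gen,
        "swissprot_only": n_swp,
        "final": len(final),
    }
    return final, counts


# ---------------------------------------------------------------------------
# TSV plumbing


def read_peptide_table(path) -> list[PeptideHit]:
    """Read a peptide-hit TSV: peptide, accession list (db:acc;db:acc), count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    hits = []
    for _, row in df.iterrows():
        accs = tuple(
            tuple(item.split(":", 1)) for item in str(row["accessions"]).split(";")
        )
        hits.append(
            PeptideHit(
                peptide=row["peptide"],
                accessions=accs,
                spectral_count=int(row.get("spectral_count", 1) or 1),
            )
        )
    return hits


def write_peptide_table(hits: Sequence[PeptideHit], path) -> None:
    rows = [
        {
            "peptide": h.peptide,
            "accessions": ";".join(f"{db}:{acc}" for db, acc in h.accessions),
            "spectral_count": h.spectral_count,
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
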