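"""The three CAFA comparison predictors: Priors, BLAST top-hit, and Gotcha.

All three score a query protein for a term using only sequence-level evidence
(or none at all): Priors scores every protein identically by the term's
background annotation frequency; BLAST transfers the percent identity of the
best annotated alignment hit; Gotcha sums -log10(E-value) over all annotated
hits and, optionally, propagates the accumulated mass up the ontology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .ontology import AnnotationTable, OntologyDAG


@dataclass(frozen=True)
class AlignmentHits:
    """Alignment hits of one query: (training protein, percent identity, E-value)."""

    query: str
    hits: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for subject, pident, evalue in self.hits:
            if evalue <= 0:
                raise ValueError(
                    f"hit {self.query!r} -> {subject!r}: E-value must be > 0, "
                    f"got {evalue}"
                )

    @classmethod
    def from_tsv(cls, path) -> dict[str, "AlignmentHits"]:
        """Read a tabular alignment file: query_id, subject_id, percent_identity, e_value."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns[:4])
        by_query: dict[str, list[tuple[str, float, float]]] = {}
        for q, s, pid, ev in df[cols].itertuples(index=False):
            by_query.setdefault(str(q), []).append((str(s), float(pid), float(ev)))
        return {q: cls(query=q, hits=tuple(hs)) for q, hs in by_query.items()}


def prior_score(f: str, ann: AnnotationTable) -> float:
    """Background probability of term ``f``: fraction of annotated proteins carrying it.

    The same value for every query protein, so the prior's ranking of
    proteins for any one term is pure ties.
    """
    if not ann.assignments:
        raise ValueError("empty annotation table")
    n = len(ann.assignments)
    return sum(1 for ts in ann.assignments.values() if f in ts) / n


def blast_score(f: str, hits: AlignmentHits, ann: AnnotationTable) -> float:
    """Identity/100 of the most similar hit annotated with ``f`` (0 if none)."""
    best = 0.0
    for subject, pident, _ in hits.hits:
        if f in ann.terms(subject):
            best = max(best, pident / 100.0)
    return best


def gotcha_score(f: str, hits: AlignmentHits, ann: AnnotationTable) -> float:
    """Sum of -log10(E-value) over hits annotated with ``f``.

    E-values >= 1 (weak hits) contribute 0 rather than a negative amount.
    """
    total = 0.0
    for subject, _, evalue in hits.hits:
        if f in ann.terms(subject):
            total += max(0.0, -math.log10(evalue))
    return total


def gotcha_score_map(
    hits: AlignmentHits,
    ann: AnnotationTable,
    dag: OntologyDAG | None = None,
) -> dict[str, float]:
    """Gotcha scores of one query for every annotated term.

    With a ``dag``, raw per-term scores are propagated cumulatively towards
    the root: each term's final score is the sum of the raw scores of the
    terms in its descendant closure (itself included), mirroring how the
    original Gotcha accumulates alignment evidence up the ontology.
    """
    raw: dict[str, float] = {}
    for subject, _, evalue in hits.hits:
        contrib = max(0.0, -math.log10(evalue))
        if contrib == 0.0:
            continue
        for t in ann.terms(subject):
            raw[t] = raw.get(t, 0.0) + contrib
    if dag is None:
        return raw
    out: dict[str, float] = {}
    for t, s in raw.items():
        for anc in dag.ancestors(t):
            out[anc] = out.get(anc, 0.0) + s
    return out
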