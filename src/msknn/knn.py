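"""Per-source kNN function-transfer scores.

The prediction score of term f for query protein p from one similarity source
is the similarity-weighted vote of p's k nearest annotated training proteins:

    score(p, f) = sum over p' in N_k(p) of sim(p, p') * [f in functions(p')]

With similarities in [0, 1] the score lies in [0, k]. A semantic variant
replaces the exact-match indicator with the Lin similarity between f and each
of the neighbor's annotated terms, so near-miss annotations still contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import (
    AnnotationTable,
    OntologyDAG,
    TermProbabilities,
    lin_similarity,
    lin_similarity_matrix,
)
from .sources import SimilaritySource

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborList:
    """The (at most) k nearest covered training proteins of one query.

    ``covered`` is False when the query is absent from the source; the
    neighbor list is then empty and every score is 0, which lets the
    integration layer apply the missing-source rule instead of failing.
    """

    query: str
    neighbors: tuple[tuple[str, float], ...]
    covered: bool = True

    def __post_init__(self) -> None:
        sims = [s for _, s in self.neighbors]
        if any(a < b for a, b in zip(sims, sims[1:])):
            raise ValueError("neighbor similarities must be non-increasing")
        if any(p == self.query for p, _ in self.neighbors):
            raise ValueError("query must not appear among its own neighbors")


@dataclass
class ScoreMatrix:
    """Proteins x terms prediction scores for one source or one integrated predictor."""

    proteins: list[str]
    terms: list[str]
    scores: np.ndarray
    source_name: str = ""
    covered: np.ndarray | None = None  # per-protein coverage flags
    _pindex: dict[str, int] = field(init=False, repr=False, compare=False)
    _tindex: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.covered is None:
            self.covered = np.ones(len(self.proteins), dtype=bool)
        if self.scores.shape != (len(self.proteins), len(self.terms)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.terms)} terms"
            )
        self._pindex = {p: i for i, p in enumerate(self.proteins)}
        self._tindex = {t: j for j, t in enumerate(self.terms)}

    def score(self, protein: str, term: str) -> float:
        return float(self.scores[self._pindex[protein], self._tindex[term]])

    def is_covered(self, protein: str) -> bool:
        return bool(self.covered[self._pindex[protein]])

    def to_tsv(self, path, decimals: int | None = None) -> None:
        """Serialize as (protein_id, term_id, score) triples, row-major."""
        rows = []
        for i, p in enumerate(self.proteins):
            for j, t in enumerate(self.terms):
                s = self.scores[i, j]
                rows.append((p, t, round(s, decimals) if decimals is not None else s))
        pd.DataFrame(rows, columns=["protein_id", "term_id", "score"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, source_name: str = "") -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "term_id": str})
        proteins = list(dict.fromkeys(df["protein_id"]))
        terms = list(dict.fromkeys(df["term_id"]))
        pidx = {p: i for i, p in enumerate(proteins)}
        tidx = {t: j for j, t in enumerate(terms)}
        scores = np.zeros((len(proteins), len(terms)))
        for p, t, s in zip(df["protein_id"], df["term_id"], df["score"]):
            scores[pidx[p], tidx[t]] = float(s)
        return cls(proteins=proteins, terms=terms, scores=scores,
                   source_name=source_name)


def nearest_neighbors(
    p: str, source: SimilaritySource, training: set[str], k: int
) -> NeighborList:
    """The k most similar covered training proteins of ``p``.

    Zero-similarity proteins are never included (a shorter list is returned
    when fewer than k proteins have positive similarity); ties at the cut are
    broken by lexicographic protein id; the query itself is excluded even when
    present in the training set. An uncovered query yields an empty list
    flagged ``covered=False``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not source.covers(p):
        return NeighborList(query=p, neighbors=(), covered=False)
    cands = sorted((training & source.covered) - {p})
    if not cands:
        return NeighborList(query=p, neighbors=())
    sims = source.sims_to(p, cands)
    order = sorted(
        (i for i in range(len(cands)) if sims[i] > 0),
        key=lambda i: (-sims[i], cands[i]),
    )[:k]
    return NeighborList(
        query=p, neighbors=tuple((cands[i], float(sims[i])) for i in order)
    )


def knn_score(p: str, f: str, nbrs: NeighborList, ann: AnnotationTable) -> float:
    """Similarity-weighted count of neighbors annotated with term ``f``."""
    return sum(s for q, s in nbrs.neighbors if f in ann.terms(q))


def linsim_knn_score(
    p: str,
    f: str,
    nbrs: NeighborList,
    ann: AnnotationTable,
    dag: OntologyDAG,
    probs: TermProbabilities,
    tau: float = 0.0,
) -> float:
    """Semantic kNN score: neighbors vote with the Lin similarity of their terms.

    Each neighbor contributes sim(p, p') times the sum of linsim(f', f) over
    its annotated terms f' with linsim >= ``tau``; cross-namespace terms
    contribute 0. With a tau that only f' = f survives, this reduces to
    :func:`knn_score`.
    """
    total = 0.0
    ns = dag.namespace[f]
    for q, s in nbrs.neighbors:
        inner = 0.0
        for fq in ann.terms(q):
            if dag.namespace[fq] != ns:
                continue
            ls = lin_similarity(fq, f, dag, probs)
            if ls >= tau:
                inner += ls
        total += s * inner
    return total


def score_all(
    queries: list[str],
    terms: list[str],
    source: SimilaritySource,
    training: set[str],
    ann: AnnotationTable,
    k: int = 20,
    mode: str = "plain",
    dag: OntologyDAG | None = None,
    probs: TermProbabilities | None = None,
    tau: float = 0.0,
) -> ScoreMatrix:
    """Vectorized kNN scoring of all query/term pairs for one source.

    ``mode='plain'`` applies the exact-match score, ``mode='linsim'`` the
    Lin-similarity-augmented score (requires ``dag`` and ``probs``). Uncovered
    queries get an all-zero row with their coverage flag cleared.
    """
    if not terms:
        raise ValueError("empty term list")
    if mode not in ("plain", "linsim"):
        raise ValueError(f"mode must be 'plain' or 'linsim', got {mode!r}")
    if mode == "linsim" and (dag is None or probs is None):
        raise ValueError("linsim mode requires dag and probs")

    train_ids = sorted(training & source.covered)
    tindex = {t: j for j, t in enumerate(terms)}
    # vote weight of training protein q for column t
    votes = np.zeros((len(train_ids), len(terms)))
    if mode == "plain":
        for i, q in enumerate(train_ids):
            for t in ann.terms(q):
                j = tindex.get(t)
                if j is not None:
                    votes[i, j] = 1.0
    else:
        ann_terms = sorted({t for q in train_ids for t in ann.terms(q)})
        ls = lin_similarity_matrix(ann_terms, terms, dag, probs)
        if tau > 0.0:
            ls = np.where(ls >= tau, ls, 0.0)
        aindex = {t: i for i, t in enumerate(ann_terms)}
        for i, q in enumerate(train_ids):
            for t in ann.terms(q):
                votes[i] += ls[aindex[t]]

    trindex = {q: i for i, q in enumerate(train_ids)}
    scores = np.zeros((len(queries), len(terms)))
    covered = np.zeros(len(queries), dtype=bool)
    for qi, p in enumerate(queries):
        nbrs = nearest_neighbors(p, source, training, k)
        covered[qi] = nbrs.covered
        if not nbrs.neighbors:
            continue
        idx = [trindex[q] for q, _ in nbrs.neighbors]
        w = np.array([s for _, s in nbrs.neighbors])
        scores[qi] = w @ votes[idx]
    if not covered.all():
        logger.info(
            "source %r: %d of %d queries uncovered",
            source.name, int((~covered).sum()), len(queries),
        )
    return ScoreMatrix(
        proteins=list(queries), terms=list(terms), scores=scores,
        source_name=source.name, covered=covered,
    )
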