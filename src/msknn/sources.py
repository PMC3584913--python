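"""Uniform [0,1] protein-protein similarity sources from heterogeneous raw data.

Three kinds of raw data are turned into :class:`SimilaritySource` objects with
a common interface: all-vs-all sequence percent identities (identity / 100),
expression matrices (Pearson correlation of profiles, negative values clipped
to 0), and protein-protein interaction edge lists (1 on an edge, 0 otherwise).
Each source carries an explicit covered-protein set, because real sources
differ widely in coverage and the integration layer treats "not covered" as a
zero score, not as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SourceError(ValueError):
    """Raised for structurally invalid raw source data."""


@dataclass
class SimilaritySource:
    """A named similarity source over a covered protein subset.

    ``matrix[i, j]`` holds sim(ids[i], ids[j]) in [0, 1]; the matrix is
    symmetric with unit diagonal.
    """

    name: str
    ids: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.ids)}
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise SourceError(
                f"source {self.name!r}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.ids)} protein ids"
            )

    @property
    def covered(self) -> set[str]:
        return set(self.ids)

    def covers(self, protein: str) -> bool:
        return protein in self._index

    def sim(self, p: str, q: str) -> float:
        return float(self.matrix[self._index[p], self._index[q]])

    def sims_to(self, p: str, others: list[str]) -> np.ndarray:
        """Vector of sim(p, q) for q in ``others`` (all must be covered)."""
        row = self.matrix[self._index[p]]
        return row[[self._index[q] for q in others]]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Proteins x samples expression values (units unconstrained)."""

    proteins: list[str]
    samples: list[str]
    values: np.ndarray

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            proteins=[str(p) for p in df.index],
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.proteins, columns=self.samples).to_csv(
            path, sep="\t", index_label="protein_id"
        )


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected PPI graph: node set plus unordered edge pairs, no self-loops."""

    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionGraph":
        nodes: set[str] = set()
        edges: set[frozenset[str]] = set()
        for a, b in pairs:
            if a == b:
                logger.warning("dropping self-loop on %r", a)
                continue
            nodes.update((a, b))
            edges.add(frozenset((a, b)))
        return cls(frozenset(nodes), frozenset(edges))

    @classmethod
    def from_tsv(cls, path) -> "InteractionGraph":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise SourceError("PPI edge list must have two columns")
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_tsv(self, path) -> None:
        rows = sorted(tuple(sorted(e)) for e in self.edges)
        pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
            path, sep="\t", index=False
        )


def identity_to_source(
    matrix: pd.DataFrame, name: str = "sequence", tol: float = 1e-6
) -> SimilaritySource:
    """Percent-identity matrix (entries in [0, 100]) -> similarity = identity/100.

    The matrix must be symmetric within ``tol`` with matching row/column ids;
    the diagonal is forced to 1.
    """
    ids = [str(i) for i in matrix.index]
    if [str(c) for c in matrix.columns] != ids:
        raise SourceError(f"source {name!r}: row and column ids differ")
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        bad = vals[(vals < 0) | (vals > 100)].flat[0]
        raise SourceError(f"source {name!r}: identity {bad} outside [0, 100]")
    if np.max(np.abs(vals - vals.T)) > tol:
        raise SourceError(f"source {name!r}: matrix asymmetric beyond tolerance {tol}")
    sim = (vals + vals.T) / 200.0
    np.fill_diagonal(sim, 1.0)
    return SimilaritySource(name=name, ids=ids, matrix=sim)


def read_identity_tsv(path, name: str = "sequence") -> SimilaritySource:
    """Read a square percent-identity TSV (header row + id column)."""
    return identity_to_source(pd.read_csv(path, sep="\t", index_col=0), name=name)


def expression_to_source(
    expr: ExpressionMatrix, name: str = "expression", keep_negative: bool = False
) -> SimilaritySource:
    """Pearson correlation of expression profiles as similarity.

    Negative correlations are clipped to 0 (keeping per-source kNN scores
    nonnegative) unless ``keep_negative`` is set. Constant rows cannot be
    correlated and are dropped from coverage with a warning. Requires >= 3
    samples.
    """
    if len(expr.samples) < 3:
        raise SourceError(
            f"source {name!r}: need >= 3 samples, got {len(expr.samples)}"
        )
    variances = expr.values.std(axis=1)
    keep = variances > 0
    if not np.all(keep):
        dropped = [p for p, k in zip(expr.proteins, keep) if not k]
        logger.warning(
            "source %r: dropping %d constant-expression protein(s): %s",
            name, len(dropped), dropped[:5],
        )
    ids = [p for p, k in zip(expr.proteins, keep) if k]
    if not ids:
        raise SourceError(f"source {name!r}: no protein with nonzero variance")
    corr = np.corrcoef(expr.values[keep])
    corr = np.atleast_2d(corr)
    sim = np.clip(corr, -1.0, 1.0)
    if not keep_negative:
        sim = np.maximum(sim, 0.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilaritySource(name=name, ids=ids, matrix=sim)


def ppi_to_source(graph: InteractionGraph, name: str = "ppi") -> SimilaritySource:
    """Binary interaction similarity: 1 on an edge, 0 otherwise.

    Coverage is restricted to nodes with degree >= 1 — an isolated node would
    emit constant-zero scores indistinguishable from "not covered".
    """
    degree: dict[str, int] = {n: 0 for n in graph.nodes}
    for e in graph.edges:
        for n in e:
            degree[n] += 1
    ids = sorted(n for n, d in degree.items() if d >= 1)
    index = {p: i for i, p in enumerate(ids)}
    sim = np.zeros((len(ids), len(ids)))
    for e in graph.edges:
        a, b = tuple(e)
        sim[index[a], index[b]] = 1.0
        sim[index[b], index[a]] = 1.0
    np.fill_diagonal(sim, 1.0)
    return SimilaritySource(name=name, ids=ids, matrix=sim)
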