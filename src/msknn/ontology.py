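"""Function ontology handling: DAG parsing, annotation propagation and Lin similarity.

Protein functions are organized in a directed acyclic graph of terms (the Gene
Ontology style), split into namespaces such as molecular function (MF) and
biological process (BP), each with a single root. Annotating a protein with a
term implicitly annotates it with every ancestor of that term up to the
namespace root (the true-path rule); most quantities in this package — term
probabilities, information content, Lin similarity — are defined on the
propagated (ancestor-closed) annotation sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical short namespace labels
_NAMESPACE_ALIASES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or annotations."""


@dataclass
class OntologyDAG:
    """A rooted, acyclic is_a hierarchy of function terms.

    Parameters
    ----------
    parents
        Map term -> set of direct is_a parents. Roots have an empty set.
    namespace
        Map term -> namespace label ("MF", "BP", ...).
    """

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _children: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            missing = ps - self.parents.keys()
            if missing:
                raise OntologyError(
                    f"term {term!r} has undeclared parent(s): {sorted(missing)}"
                )
        cycle = self._find_cycle()
        if cycle is not None:
            raise OntologyError(f"cycle detected through edge {cycle[0]} -> {cycle[1]}")
        roots: dict[str, str] = {}
        for term, ps in self.parents.items():
            if not ps:
                ns = self.namespace[term]
                if ns in roots:
                    raise OntologyError(
                        f"namespace {ns!r} has multiple roots: {roots[ns]!r}, {term!r}"
                    )
                roots[ns] = term
        self.roots: dict[str, str] = roots

    def _find_cycle(self) -> tuple[str, str] | None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for term, ps in self.parents.items():
            g.add_edges_from((term, p) for p in ps)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return (cyc[0][0], cyc[0][1])

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def root_of(self, term: str) -> str:
        return self.roots[self.namespace[term]]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including ``term`` itself (reflexive closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        anc = {term}
        for p in self.parents[term]:
            anc |= self.ancestors(p)
        result = frozenset(anc)
        self._ancestor_cache[term] = result
        return result

    def children(self, term: str) -> set[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.parents}
            for t, ps in self.parents.items():
                for p in ps:
                    ch[p].add(t)
            self._children = ch
        return self._children[term]

    def leaves(self) -> set[str]:
        return {t for t in self.parents if not self.children(t)}


@dataclass(frozen=True)
class AnnotationTable:
    """Protein -> set-of-terms assignments, raw or ancestor-closed."""

    assignments: dict[str, frozenset[str]]
    propagated: bool = False

    @property
    def proteins(self) -> set[str]:
        return set(self.assignments)

    def terms(self, protein: str) -> frozenset[str]:
        return self.assignments.get(protein, frozenset())

    def annotated_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.assignments.values():
            out |= ts
        return out

    @classmethod
    def from_tsv(cls, path, propagated: bool = False) -> "AnnotationTable":
        """Read a protein_id / term_id (/ evidence_code) TSV with a header line."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"protein_id", "term_id"}
        if not required.issubset(df.columns):
            raise OntologyError(
                f"annotation TSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        assignments: dict[str, set[str]] = {}
        for prot, term in zip(df["protein_id"], df["term_id"]):
            assignments.setdefault(prot, set()).add(term)
        return cls(
            {p: frozenset(ts) for p, ts in assignments.items()}, propagated=propagated
        )

    def to_tsv(self, path) -> None:
        rows = [
            (p, t)
            for p in sorted(self.assignments)
            for t in sorted(self.assignments[p])
        ]
        pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class TermProbabilities:
    """Per-term annotation probabilities p(f), estimated from a propagated corpus."""

    p: dict[str, float]
    n_proteins: int

    def __getitem__(self, term: str) -> float:
        return self.p[term]


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Only ``is_a`` relations are honored; obsolete terms are dropped. An
    ``is_a`` target that is never declared as a term, or a cycle, is a hard
    error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    declared = {n for n, data in graph.nodes(data=True) if data}
    for node in declared:
        # obonet stores edges child -> parent, keyed by relation type
        ps = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        undeclared = ps - declared
        if undeclared:
            raise OntologyError(
                f"term {node!r} has undeclared is_a target(s): {sorted(undeclared)}"
            )
        parents[node] = ps
        ns = graph.nodes[node].get("namespace", "")
        namespace[node] = _NAMESPACE_ALIASES.get(ns, ns or "default")
    return OntologyDAG(parents=parents, namespace=namespace)


def propagate(ann: AnnotationTable, dag: OntologyDAG) -> AnnotationTable:
    """Ancestor-close every protein's term set (true-path rule). Idempotent."""
    unknown = ann.annotated_terms() - dag.terms
    if unknown:
        raise OntologyError(f"annotations to unknown terms: {sorted(unknown)}")
    closed = {
        p: frozenset().union(*(dag.ancestors(t) for t in ts)) if ts else frozenset()
        for p, ts in ann.assignments.items()
    }
    return AnnotationTable(closed, propagated=True)


def estimate_term_probabilities(
    ann: AnnotationTable, dag: OntologyDAG, epsilon: float = 1e-9
) -> TermProbabilities:
    """Estimate p(f) = fraction of annotated proteins carrying term f.

    Requires a propagated table so that p is monotone non-increasing from
    parent to child. Counts are normalized per namespace — the denominator
    for f is the number of proteins with at least one annotation in f's
    namespace — so every namespace root gets probability exactly 1 and Lin
    similarity vanishes when the minimum subsumer is the root. Zero-count
    terms are floored at ``epsilon`` so logarithms stay finite.
    """
    if not ann.assignments:
        raise OntologyError("cannot estimate term probabilities from an empty table")
    if not ann.propagated:
        raise OntologyError("term probabilities require a propagated annotation table")
    counts: dict[str, int] = {t: 0 for t in dag.terms}
    ns_totals: dict[str, int] = {ns: 0 for ns in dag.roots}
    for ts in ann.assignments.values():
        for t in ts:
            counts[t] += 1
        for ns in {dag.namespace[t] for t in ts}:
            ns_totals[ns] += 1
    p = {}
    for t, c in counts.items():
        denom = ns_totals.get(dag.namespace[t], 0)
        p[t] = c / denom if c > 0 and denom > 0 else epsilon
    return TermProbabilities(p=p, n_proteins=len(ann.assignments))


def min_subsumer_probability(
    f: str, g: str, dag: OntologyDAG, probs: TermProbabilities
) -> float:
    """p_ms(f, g): the minimum of p over the common ancestors of f and g.

    Ancestor sets are reflexive (a term is its own ancestor), so
    ``min_subsumer_probability(f, f) == p(f)``. The namespace root is common
    to every same-namespace pair, so the result is always well defined.
    """
    if dag.namespace[f] != dag.namespace[g]:
        raise OntologyError(
            f"terms {f!r} ({dag.namespace[f]}) and {g!r} ({dag.namespace[g]}) "
            "are in different namespaces"
        )
    common = dag.ancestors(f) & dag.ancestors(g)
    return min(probs.p[t] for t in common)


def lin_similarity(
    f: str, g: str, dag: OntologyDAG, probs: TermProbabilities
) -> float:
    """Lin's information-theoretic similarity between two same-namespace terms.

    linsim(f, g) = 2 log p_ms(f, g) / (log p(f) + log p(g)), where p_ms is the
    probability of the minimum subsumer (the least-probable common ancestor).
    By construction linsim(f, f) = 1 and linsim = 0 whenever the only
    informative common ancestor is the root (p_ms = 1). The log base cancels.
    """
    if dag.namespace[f] != dag.namespace[g]:
        raise OntologyError(f"cross-namespace pair ({f!r}, {g!r})")
    if f == g:
        return 1.0
    pms = min_subsumer_probability(f, g, dag, probs)
    num = 2.0 * math.log(pms)
    if num == 0.0:  # minimum subsumer is the root
        return 0.0
    den = math.log(probs.p[f]) + math.log(probs.p[g])
    if den == 0.0:  # both probabilities 1 but f != g: degenerate, no information
        return 0.0
    return min(1.0, max(0.0, num / den))


def lin_similarity_matrix(
    terms_a: list[str],
    terms_b: list[str],
    dag: OntologyDAG,
    probs: TermProbabilities,
):
    """Dense |terms_a| x |terms_b| matrix of Lin similarities.

    Cross-namespace pairs get similarity 0 (rather than an error) so the
    matrix can span a whole multi-namespace ontology.
    """
    import numpy as np

    out = np.zeros((len(terms_a), len(terms_b)))
    for i, fa in enumerate(terms_a):
        for j, fb in enumerate(terms_b):
            if dag.namespace[fa] != dag.namespace[fb]:
                continue
            out[i, j] = lin_similarity(fa, fb, dag, probs)
    return out


def cluster_terms(dag: OntologyDAG, level: str = "root") -> dict[str, str]:
    """Assign every term to a cluster at the root or first ontology level.

    ``root``: cluster = namespace (MF vs BP). ``first``: cluster = the direct
    child of the root that subsumes the term; a term under several first-level
    children maps to the lexicographically smallest, and the roots themselves
    map to their namespace.
    """
    if level not in ("root", "first"):
        raise ValueError(f"level must be 'root' or 'first', got {level!r}")
    if level == "root":
        return {t: dag.namespace[t] for t in dag.terms}
    clusters: dict[str, str] = {}
    first_level = {
        ns: dag.children(root) for ns, root in dag.roots.items()
    }
    for t in dag.terms:
        ns = dag.namespace[t]
        root = dag.roots[ns]
        if t == root:
            clusters[t] = ns
            continue
        hits = dag.ancestors(t) & first_level[ns]
        clusters[t] = min(hits) if hits else ns
    return clusters
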