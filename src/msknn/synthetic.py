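"""Synthetic ontology, annotations and data sources with planted functional signal.

The generator emulates the shape of a real function-prediction corpus without
any download: a two-namespace is_a DAG (molecular-function-like and
biological-process-like), proteins annotated with leaf terms drawn from
latent "functional modules", and three correlated similarity sources —
sequence identities boosted for proteins sharing annotations, expression
profiles shared within a module plus Gaussian noise, and a PPI graph whose
edge probability is elevated for functionally related pairs. Each source
covers only a seeded random subset of proteins, mirroring the very uneven
coverage of real sequence/microarray/PPI corpora.

A single global seed fans out to per-component child seeds, so every file is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import AnnotationTable, OntologyDAG
from .sources import ExpressionMatrix, InteractionGraph

_NS_LONG = {"MF": "molecular_function", "BP": "biological_process"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults give a desk-scale corpus on which kNN label transfer is
    learnable but not trivial: 300 proteins, 60 terms in two namespaces,
    8 latent functional modules, and per-source coverages echoing the
    all/partial/sparse split of real sequence/expression/PPI data.
    """

    n_proteins: int = 300
    n_terms: int = 60
    dag_branching: int = 3
    annotation_rate: float = 1.0
    n_modules: int = 8
    n_samples: int = 40
    multi_parent_fraction: float = 0.1
    signal: dict[str, float] = field(
        default_factory=lambda: {"sequence": 0.8, "expression": 0.7, "ppi": 0.7}
    )
    coverage: dict[str, float] = field(
        default_factory=lambda: {"sequence": 1.0, "expression": 0.46, "ppi": 0.20}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if self.n_terms < 3:
            raise ValueError(f"n_terms must be >= 3, got {self.n_terms}")
        for name, rate in [
            ("annotation_rate", self.annotation_rate),
            ("multi_parent_fraction", self.multi_parent_fraction),
            *((f"signal[{k}]", v) for k, v in self.signal.items()),
            *((f"coverage[{k}]", v) for k, v in self.coverage.items()),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")

    def child_rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _term_id(i: int) -> str:
    return f"SX:{i:07d}"


def protein_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"P{i:04d}" for i in range(cfg.n_proteins)]


def protein_modules(cfg: SyntheticConfig) -> dict[str, int]:
    """Deterministic latent functional-module assignment (round-robin)."""
    return {p: i % cfg.n_modules for i, p in enumerate(protein_ids(cfg))}


def make_ontology(cfg: SyntheticConfig) -> OntologyDAG:
    """Two-namespace DAG: balanced b-ary trees plus a few second parents.

    Terms are split evenly between the MF-like and BP-like namespaces; each
    namespace is a ``dag_branching``-ary tree, and a seeded fraction of
    deeper terms gains a second parent (an earlier same-namespace term) to
    exercise multi-parent ancestor logic while staying acyclic.
    """
    rng = cfg.child_rng(1)
    n_mf = cfg.n_terms // 2
    groups = {"MF": list(range(n_mf)), "BP": list(range(n_mf, cfg.n_terms))}
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for ns, idxs in groups.items():
        if not idxs:
            continue
        for local, i in enumerate(idxs):
            t = _term_id(i)
            namespace[t] = ns
            if local == 0:
                parents[t] = set()
            else:
                parent_local = (local - 1) // cfg.dag_branching
                parents[t] = {_term_id(idxs[parent_local])}
        # second parents: edge to an earlier term keeps the graph acyclic
        for local, i in enumerate(idxs):
            if local <= cfg.dag_branching:
                continue
            if rng.random() < cfg.multi_parent_fraction:
                choice = idxs[int(rng.integers(1, local))]
                if _term_id(choice) not in parents[_term_id(i)]:
                    parents[_term_id(i)].add(_term_id(choice))
    return OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace=namespace,
    )


def make_annotations(dag: OntologyDAG, cfg: SyntheticConfig) -> AnnotationTable:
    """Raw (leaf-level) annotations driven by latent functional modules.

    Leaves are partitioned round-robin into ``n_modules`` pools; each
    annotated protein draws 1-5 leaves mostly from its module's pool, with a
    10% chance of one extra random leaf, so module-mates share terms and
    every pool's terms accumulate many proteins (keeping terms eligible for
    term-centric AUC at desk scale).
    """
    rng = cfg.child_rng(2)
    leaves = sorted(dag.leaves())
    pools = [leaves[m :: cfg.n_modules] for m in range(cfg.n_modules)]
    pools = [pool if pool else leaves for pool in pools]
    modules = protein_modules(cfg)
    assignments: dict[str, frozenset[str]] = {}
    for p in protein_ids(cfg):
        if rng.random() > cfg.annotation_rate:
            continue
        pool = pools[modules[p]]
        n_draw = int(rng.integers(1, 6))
        chosen = set(rng.choice(pool, size=min(n_draw, len(pool)), replace=False))
        if rng.random() < 0.1:
            chosen.add(leaves[int(rng.integers(0, len(leaves)))])
        assignments[p] = frozenset(chosen)
    return AnnotationTable(assignments, propagated=False)


def _covered_subset(
    proteins: list[str], fraction: float, rng: np.random.Generator
) -> list[str]:
    n = max(1, int(round(fraction * len(proteins))))
    if n >= len(proteins):
        return list(proteins)
    return sorted(rng.choice(proteins, size=n, replace=False))


def make_sources(
    ann: AnnotationTable, cfg: SyntheticConfig
) -> tuple[pd.DataFrame, ExpressionMatrix, InteractionGraph]:
    """Three raw data sources with signal planted from the annotations.

    * sequence: percent identity = uniform noise in [5, 25] plus a bonus of
      up to 70 points proportional to ``signal`` times the Jaccard overlap of
      the two proteins' leaf-term sets, clipped to [0, 100], diagonal 100;
    * expression: row = signal x latent module profile + unit Gaussian noise
      over ``n_samples`` samples, so module-mates correlate positively;
    * PPI: edge probability 0.01, raised by 0.35 x signal when the pair
      shares at least one leaf term.

    Each source is restricted to its seeded covered subset of proteins.
    """
    proteins = sorted(ann.assignments)
    leaf_sets = {p: set(ann.assignments[p]) for p in proteins}
    modules = protein_modules(cfg)

    rng_cov = cfg.child_rng(3)
    cov_seq = _covered_subset(proteins, cfg.coverage["sequence"], rng_cov)
    cov_expr = _covered_subset(proteins, cfg.coverage["expression"], rng_cov)
    cov_ppi = _covered_subset(proteins, cfg.coverage["ppi"], rng_cov)

    # sequence identities
    rng = cfg.child_rng(4)
    n = len(cov_seq)
    ident = rng.uniform(5.0, 25.0, size=(n, n))
    ident = (ident + ident.T) / 2.0
    s = cfg.signal["sequence"]
    for i, p in enumerate(cov_seq):
        for j in range(i + 1, n):
            q = cov_seq[j]
            a, b = leaf_sets[p], leaf_sets[q]
            union = len(a | b)
            if union:
                bonus = 70.0 * s * len(a & b) / union
                ident[i, j] += bonus
                ident[j, i] += bonus
    ident = np.clip(ident, 0.0, 100.0)
    np.fill_diagonal(ident, 100.0)
    identity = pd.DataFrame(ident, index=cov_seq, columns=cov_seq)

    # expression
    rng = cfg.child_rng(5)
    profiles = rng.normal(0.0, 1.0, size=(cfg.n_modules, cfg.n_samples))
    se = cfg.signal["expression"]
    values = np.vstack(
        [
            se * profiles[modules[p]]
            + rng.normal(0.0, 1.0, size=cfg.n_samples)
            for p in cov_expr
        ]
    )
    expr = ExpressionMatrix(
        proteins=list(cov_expr),
        samples=[f"S{j:03d}" for j in range(cfg.n_samples)],
        values=values,
    )

    # PPI
    rng = cfg.child_rng(6)
    sp = cfg.signal["ppi"]
    pairs = []
    for i, p in enumerate(cov_ppi):
        for q in cov_ppi[i + 1 :]:
            prob = 0.01 + (0.35 * sp if leaf_sets[p] & leaf_sets[q] else 0.0)
            if rng.random() < prob:
                pairs.append((p, q))
    graph = InteractionGraph.from_pairs(pairs)
    return identity, expr, graph


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize a DAG as a minimal OBO 1.2 flat file."""
    lines = ["format-version: 1.2", "ontology: synthetic-function-ontology", ""]
    for t in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: synthetic term {t}")
        ns = dag.namespace[t]
        lines.append(f"namespace: {_NS_LONG.get(ns, ns)}")
        for p in sorted(dag.parents[t]):
            lines.append(f"is_a: {p} ! synthetic term {p}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_dataset(cfg: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate and write a full corpus; returns the file manifest.

    Files: ontology.obo, annotations.tsv, identity.tsv, expression.tsv,
    ppi.tsv, manifest.json (the config used).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = make_ontology(cfg)
    ann = make_annotations(dag, cfg)
    identity, expr, graph = make_sources(ann, cfg)

    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "identity": outdir / "identity.tsv",
        "expression": outdir / "expression.tsv",
        "ppi": outdir / "ppi.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_obo(dag, paths["ontology"])
    ann.to_tsv(paths["annotations"])
    identity.to_csv(paths["identity"], sep="\t", index_label="protein_id")
    expr.to_tsv(paths["expression"])
    graph.to_tsv(paths["ppi"])
    manifest = dataclasses.asdict(cfg)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
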