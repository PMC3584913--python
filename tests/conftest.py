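import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msknn import (
    AnnotationTable,
    OntologyDAG,
    SyntheticConfig,
    estimate_term_probabilities,
    make_annotations,
    make_ontology,
    make_sources,
    propagate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_dag():
    """root -> a -> b -> c linear chain in one namespace."""
    return OntologyDAG(
        parents={
            "root": frozenset(),
            "a": frozenset({"root"}),
            "b": frozenset({"a"}),
            "c": frozenset({"b"}),
        },
        namespace={t: "MF" for t in ("root", "a", "b", "c")},
    )


@pytest.fixture
def diamond_dag():
    """Two namespaces; MF has a diamond (d under both b and c, which share a)."""
    mf = {
        "mf_root": frozenset(),
        "a": frozenset({"mf_root"}),
        "b": frozenset({"a"}),
        "c": frozenset({"a"}),
        "d": frozenset({"b", "c"}),
        "e": frozenset({"mf_root"}),
    }
    bp = {"bp_root": frozenset(), "x": frozenset({"bp_root"})}
    ns = {t: "MF" for t in mf} | {t: "BP" for t in bp}
    return OntologyDAG(parents=mf | bp, namespace=ns)


def random_dag(rng: np.random.Generator, n_terms: int = 20) -> OntologyDAG:
    """A random single-namespace DAG; parent indices are always smaller, so acyclic."""
    parents = {"t000": frozenset()}
    for i in range(1, n_terms):
        n_par = 1 + (rng.random() < 0.3)
        ps = rng.choice(i, size=min(n_par, i), replace=False)
        parents[f"t{i:03d}"] = frozenset(f"t{j:03d}" for j in ps)
    return OntologyDAG(parents=parents, namespace={t: "MF" for t in parents})


def random_propagated_table(
    rng: np.random.Generator, dag: OntologyDAG, n_proteins: int = 30
) -> AnnotationTable:
    terms = sorted(dag.terms)
    assignments = {}
    for i in range(n_proteins):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(terms, size=k, replace=False)
        assignments[f"P{i:03d}"] = frozenset(chosen)
    return propagate(AnnotationTable(assignments), dag)


@pytest.fixture(scope="session")
def small_corpus():
    """A small but complete synthetic corpus shared across tests."""
    cfg = SyntheticConfig(n_proteins=80, n_terms=30, seed=11)
    dag = make_ontology(cfg)
    ann = make_annotations(dag, cfg)
    prop = propagate(ann, dag)
    identity, expr, graph = make_sources(ann, cfg)
    probs = estimate_term_probabilities(prop, dag)
    return {
        "cfg": cfg, "dag": dag, "ann": ann, "prop": prop,
        "identity": identity, "expr": expr, "graph": graph, "probs": probs,
    }
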