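"""Generate a synthetic function-prediction corpus and inspect its shape.

Writes an ontology (OBO), leaf-level protein annotations, and three raw data
sources (sequence identities, expression matrix, PPI edge list) with planted
functional signal, then reports their coverage.
"""

from msknn import SyntheticConfig, make_annotations, make_ontology, make_sources

cfg = SyntheticConfig(n_proteins=200, n_terms=40, seed=42)
dag = make_ontology(cfg)
ann = make_annotations(dag, cfg)
identity, expr, graph = make_sources(ann, cfg)

print(f"ontology: {len(dag.terms)} terms, roots {sorted(dag.roots.values())}")
print(f"annotated proteins: {len(ann.assignments)}")
print(f"sequence identities: {identity.shape[0]} x {identity.shape[1]} matrix")
print(f"expression: {len(expr.proteins)} proteins x {len(expr.samples)} samples")
ppi_nodes = set().union(*graph.edges) if graph.edges else set()
print(f"ppi: {len(graph.edges)} interactions over {len(ppi_nodes)} proteins")
print()
print("Each source covers a different protein subset (sequence covers all,")
print("expression and PPI only fractions), mimicking real corpora where a")
print("query protein may be missing from most data types.")
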