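"""Full pipeline on planted data: simulate, score per source, integrate, evaluate.

Generates a 300-protein corpus, holds out 100 proteins, scores them with
k = 20 nearest neighbors per source, averages the three sources, and
compares macro term-centric AUC of each single source against the
integrated predictor.
"""

import numpy as np

from msknn import (
    AnnotationTable,
    GoldStandard,
    SyntheticConfig,
    average_scores,
    expression_to_source,
    identity_to_source,
    make_annotations,
    make_ontology,
    make_sources,
    ppi_to_source,
    propagate,
    score_all,
    term_auc,
)

cfg = SyntheticConfig(n_proteins=300, seed=7)
dag = make_ontology(cfg)
ann = make_annotations(dag, cfg)
prop = propagate(ann, dag)
identity, expr, graph = make_sources(ann, cfg)
srcs = {
    "sequence": identity_to_source(identity),
    "ppi": ppi_to_source(graph),
    "expression": expression_to_source(expr),
}

rng = np.random.default_rng(7)
proteins = sorted(ann.assignments)
test = sorted(rng.choice(proteins, size=100, replace=False))
training = set(proteins) - set(test)
train_ann = AnnotationTable(
    {p: prop.assignments[p] for p in training}, propagated=True
)
terms = sorted({t for p in training for t in prop.assignments[p]})

sms = {name: score_all(test, terms, src, training, train_ann, k=20)
       for name, src in srcs.items()}
ms = average_scores(sms["sequence"], sms["ppi"], [sms["expression"]])
gold = GoldStandard.from_annotations(
    AnnotationTable({p: prop.assignments[p] for p in test}, propagated=True),
    min_count=5,
)

print(f"{'predictor':<12} macro TermAUC")
for name, sm in {**sms, "ms-knn": ms}.items():
    _, macro = term_auc(sm, gold)
    print(f"{name:<12} {macro:.3f}")
print()
print("Each row is the mean, over eligible terms, of the ROC AUC obtained by")
print("ranking the 100 held-out proteins for that term. PPI covers only 20%")
print("of proteins, so alone it is near chance; averaging the three sources")
print("stays far above the weakest source and close to the strongest.")
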