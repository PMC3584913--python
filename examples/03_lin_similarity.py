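"""Term probabilities and Lin semantic similarity on a small ontology chain.

Builds root -> a -> b with hand-set annotation counts, estimates per-term
probabilities, and evaluates linsim = 2 log p_ms / (log p(f) + log p(f')).
"""

from msknn import (
    AnnotationTable,
    OntologyDAG,
    estimate_term_probabilities,
    lin_similarity,
    min_subsumer_probability,
    propagate,
)

dag = OntologyDAG(
    parents={"root": frozenset(), "a": frozenset({"root"}),
             "b": frozenset({"a"}), "e": frozenset({"root"})},
    namespace={t: "MF" for t in ("root", "a", "b", "e")},
)
# 12 proteins: 3 at leaf b, 3 more at a, 2 at e, 4 only at the root
assignments = {f"pb{i}": frozenset({"b"}) for i in range(3)}
assignments |= {f"pa{i}": frozenset({"a"}) for i in range(3)}
assignments |= {f"pe{i}": frozenset({"e"}) for i in range(2)}
assignments |= {f"pr{i}": frozenset({"root"}) for i in range(4)}
ann = propagate(AnnotationTable(assignments), dag)
probs = estimate_term_probabilities(ann, dag)

print("term probabilities (fraction of annotated proteins carrying the term):")
for t in ("root", "a", "b", "e"):
    print(f"  p({t}) = {probs[t]:.3f}")
print()
print(f"p_ms(b, a) = {min_subsumer_probability('b', 'a', dag, probs):.3f}  "
      "(least-probable common ancestor: a)")
print(f"linsim(b, a) = {lin_similarity('b', 'a', dag, probs):.4f}")
print(f"linsim(b, b) = {lin_similarity('b', 'b', dag, probs):.4f}  (identity)")
print(f"linsim(b, e) = {lin_similarity('b', 'e', dag, probs):.4f}  "
      "(only common ancestor is the root)")
print()
print("Similarity is 1 for identical terms, 0 when terms share nothing but")
print("the root, and in between scales with how informative (rare) the")
print("deepest shared ancestor is.")
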