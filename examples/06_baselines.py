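"""The three comparison baselines: Priors, BLAST top-hit and Gotcha.

Scores one query protein for a term from a toy table of alignment hits
against an annotated training set.
"""

from msknn import (
    AlignmentHits,
    AnnotationTable,
    blast_score,
    gotcha_score,
    prior_score,
)

ann = AnnotationTable(
    {
        "TRYP_PIG": frozenset({"peptidase"}),
        "TRYP_BOVIN": frozenset({"peptidase"}),
        "ALBU_HUMAN": frozenset({"transport"}),
        "HBA_HUMAN": frozenset({"transport"}),
        "CYC_HUMAN": frozenset({"electron_carrier"}),
    },
    propagated=True,
)
hits = AlignmentHits(
    "QUERY",
    (
        ("TRYP_PIG", 82.0, 1e-40),
        ("TRYP_BOVIN", 78.5, 1e-35),
        ("ALBU_HUMAN", 22.0, 0.8),
    ),
)

term = "peptidase"
print(f"scores of QUERY for term {term!r}:")
print(f"  prior  = {prior_score(term, ann):.2f}   "
      "(background frequency; same for every query)")
print(f"  blast  = {blast_score(term, hits, ann):.2f}   "
      "(identity/100 of the best annotated hit)")
print(f"  gotcha = {gotcha_score(term, hits, ann):.1f}   "
      "(sum of -log10 E-values over annotated hits)")
print()
print("BLAST uses only the single best hit; Gotcha accumulates evidence from")
print("every annotated hit, so two strong trypsin alignments yield a large")
print("score; the prior ignores the query entirely.")
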