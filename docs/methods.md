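# Methods

## The prediction model

`msknn` predicts protein function as a multi-label problem over a GO-style
ontology DAG. For one similarity source, the score of term *f* for query
protein *p* is a similarity-weighted vote of the *k* most similar annotated
training proteins:

    score(p, f) = Σ_{p' ∈ N_k(p)} sim(p, p') · I(f ∈ functions(p'))

with sim in [0, 1], so scores lie in [0, k]. Three raw data types are mapped
onto this common similarity interface:

* **sequence** — percent identity / 100;
* **expression** — Pearson correlation of expression profiles, negative
  values clipped to 0 (see *Numerical choices*);
* **PPI** — 1 if two proteins interact, 0 otherwise.

A semantic variant replaces the exact-match indicator with Lin similarity, so
neighbors annotated with *related* terms still contribute:

    score(p, f) = Σ_{p'} sim(p, p') Σ_{f' ∈ functions(p')} linsim(f', f),
    linsim(f, f') = 2 log p_ms(f, f') / (log p(f) + log p(f'))

where p(f) is the probability of a protein being annotated with f and
p_ms is the minimum of p over the common ancestors of f and f' (ancestor
sets are reflexive, so linsim(f, f) = 1; when the only common ancestor is
the root, p_ms = 1 and linsim = 0). A threshold `tau` discards inner-sum
contributions with linsim below it.

### Integration

Per-source score matrices are combined three ways:

1. **averaging** (the default): one third each to sequence, PPI and the mean
   of the J expression-dataset scores — score = ⅓·seq + ⅓·ppi + 1/(3J)·Σ exp.
   A source that does not cover a protein contributes 0, so proteins seen by
   several sources score systematically higher; this is deliberate — extra
   coverage is extra confidence.
2. **learned global weights**: weights on the probability simplex minimizing
   the rank hinge loss Σ ξ(y, ȳ), ξ = max(0, −w·(f(x,y) − f(x,ȳ))), over all
   (annotated, unannotated) term pairs of training proteins — a linear
   program.
3. **cluster-specific weights**: the same LP solved independently per term
   cluster (namespace roots, or their direct children), applied to every
   descendant term of the cluster.

### Baselines and evaluation

Priors (term background frequency, identical for every query), BLAST
top-hit (identity/100 of the best annotated hit) and Gotcha
(Σ −log10 E-value over annotated hits, optionally accumulated up the
ontology) serve as comparison predictors. Evaluation offers term-centric
ROC AUC (Mann–Whitney rank statistic, ties counted 0.5) macro-averaged over
terms annotated to more than `min_count` test proteins, and three
protein-centric precision/recall sweeps: score-threshold (predicted set =
ancestor closure of above-threshold terms), top-N (the N highest-scoring
terms, ties at the cut all retained), and IC-weighted threshold (terms
counted by −log annotation frequency instead of 1).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 20 | neighbors per query; per-source scores live in [0, k] |
| `tau` | 0 | Lin-similarity floor in the semantic inner sum |
| `epsilon` | 1e-9 | probability floor for unannotated terms (keeps logs finite) |
| `min_count` | 25 | test-protein count above which a term enters TermAUC |
| `max_pairs` | 10,000 | seeded subsample cap on rank-loss (y, ȳ) pairs |
| truncation limit | 1,000 | maximum submitted terms per protein |

## Numerical and design choices

* **Log base.** Natural log everywhere it cancels (Lin similarity, IC);
  base 10 for Gotcha, the E-value convention. Only scales, never orderings,
  depend on these.
* **Per-namespace probability normalization.** p(f) is computed over
  proteins with at least one annotation in f's namespace, so each namespace
  root has p = 1 exactly and linsim is 0 at the root even when some
  proteins are annotated only in the other namespace.
* **Degenerate Lin cases.** linsim(f, f) = 1 by convention even at p = 1;
  distinct terms with both probabilities 1 get 0 (no information, the
  conservative choice). Values are clamped to [0, 1] against floating-point
  spill.
* **Negative expression correlations** are clipped to 0: per-source scores
  must stay nonnegative for the [0, k] score range and the missing-source
  zero rule to make sense. `keep_negative=True` disables clipping for
  experimentation.
* **Neighbor selection.** Zero-similarity proteins never enter a neighbor
  list (they contribute nothing but would make tie-breaking arbitrary, e.g.
  for binary PPI similarities); ties at the cut break by lexicographic
  protein id; a query present in the training set is excluded from its own
  neighbors. Uncovered queries yield an all-zero, flagged row rather than an
  error, so integration can apply the zero rule.
* **Rank-loss LP.** Solved with HiGHS via `scipy.optimize.linprog`.
  Negatives Ȳ are restricted to terms annotated in at least one other
  training protein — a missing annotation is weak evidence of absence, and
  never-annotated terms would flood the pair set. The optimum in w is often
  a face of the simplex (duplicated sources give a perfectly flat
  objective), so a second LP stage canonicalizes deterministically:
  among loss-optimal weight vectors, maximize the weight of the source with
  the smallest single-source hinge loss (ties broken by source order). A
  perfectly informative source therefore receives weight exactly 1, and
  flat objectives return a vertex, not an arbitrary interior point.
* **Training-annotation propagation** is exposed as a flag: the plain kNN
  vote benefits from ancestor-closed training annotations (ancestor terms
  get meaningful scores), while the semantic inner sum defaults to raw leaf
  annotations to avoid double-counting a leaf and its ancestors.
* **Threshold grids** default to 101 quantiles of the observed score
  distribution; kNN scores are unnormalized sums, so a fixed 0–1 grid would
  collapse onto few effective thresholds. Proteins with no above-threshold
  prediction are skipped from the averages at that threshold. Curve areas
  are trapezoids over the recall-ordered (recall, precision) points; the raw
  curves are always returned so any other integration convention can be
  recomputed.
* **Tau = 1 reduction.** The semantic score reduces exactly to the plain
  score at tau = 1 for terms whose only linsim-1 partner is themselves;
  distinct nested terms with equal annotation probabilities also reach
  linsim 1 and legitimately keep contributing.
* **Submission truncation** keeps the top 1,000 positive-score terms per
  protein, ties broken by term id; zero-score rows are never emitted.

## The synthetic generator

The generator emulates the *shape* of a real corpus, not its biology: a
two-namespace is_a DAG (balanced b-ary trees plus a seeded fraction of
second parents), proteins assigned to latent functional modules that drive
1–5 leaf annotations each, and three sources whose signal derives from the
annotations — identity noise in [5, 25] plus up to 70 points times the
Jaccard overlap of leaf-term sets, expression rows = signal × shared module
profile + unit Gaussian noise, and PPI edges at probability 0.01 raised by
0.35 × signal for pairs sharing a leaf term. Coverage defaults
(sequence 1.0, expression 0.46, PPI 0.20) echo the uneven coverage of real
sequence/microarray/interaction data. A single seed fans out to
per-component child generators, so all outputs are byte-reproducible.

What it does **not** model: sequence evolution (identities are exchangeable
noise plus bonus, not alignments), microarray platform artifacts,
annotation bias toward well-studied proteins, and inter-term correlation
beyond the module structure. Passing tests on planted data therefore show
that the implementation recovers signal *of the planted form*; they say
nothing about accuracy on real corpora, where the relative strength of the
three sources is an empirical question.

Test and demonstration problem sizes were chosen for quick laptop runs:
corpora of 300 proteins / 60 terms (full-pipeline studies, 100 held-out
test proteins, `min_count` 5) down to 20–80 proteins for unit tests; LP
oracle checks use m ≤ 3 sources with grids at resolution 1e-3.

## Known limitations

* The rank-loss formulation treats every unannotated term as a negative;
  incomplete annotation therefore biases learned weights, which is visible
  on real data (weighted variants need not beat plain averaging) and is the
  reason the plain average is the default integrator.
* PPI reliability weighting is deliberately not implemented; interactions
  are binary.
* Probe-level expression ID mapping is out of scope; multiple profiles per
  protein must be aggregated upstream (the expression reader takes one row
  per protein).
* Only `is_a` edges are honored; `part_of` and other relations are ignored
  at parse time.
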