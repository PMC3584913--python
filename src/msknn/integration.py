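"""Integration of per-source kNN scores into one prediction.

Three schemes, in increasing sophistication:

* plain averaging (MS-kNN): one third each to the sequence score, the PPI
  score and the mean of the J expression-dataset scores; an uncovered source
  contributes 0, biasing multi-source proteins upward by design;
* globally weighted averaging (MS-W-kNN): source weights on the probability
  simplex learned by minimizing a rank hinge loss — for every training
  protein, every (annotated, unannotated) term pair should be ranked
  correctly by the weighted score;
* cluster-specific weights (MS-CW-kNN): the same rank loss solved
  independently per ontology term cluster (namespace roots or their direct
  children), so e.g. molecular-function terms may weight sequence more
  heavily than process terms do.

The rank-loss problem is a linear program: minimize the sum of slacks
xi(y, ybar) >= -(w . (f(x, y) - f(x, ybar))) subject to w on the simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .knn import ScoreMatrix
from .ontology import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightVector:
    """Per-source nonnegative weights summing to 1, with the achieved rank loss."""

    source_names: tuple[str, ...]
    w: np.ndarray
    objective: float | None = None

    def __post_init__(self) -> None:
        if len(self.w) != len(self.source_names):
            raise ValueError("weight/source length mismatch")
        if np.any(self.w < -1e-12):
            raise ValueError(f"negative weight in {self.w}")
        if abs(float(np.sum(self.w)) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {np.sum(self.w)}")

    def as_dict(self) -> dict[str, float]:
        return {n: float(x) for n, x in zip(self.source_names, self.w)}

    @classmethod
    def uniform(cls, source_names) -> "WeightVector":
        names = tuple(source_names)
        m = len(names)
        return cls(names, np.full(m, 1.0 / m))


@dataclass(frozen=True)
class RankLossProblem:
    """Training data for rank-loss weight learning.

    ``deltas`` stacks one row per (protein, positive term y, negative term
    ybar) pair: f(x, y) - f(x, ybar), an m-vector of per-source score
    differences. ``pair_terms`` records the positive term of each row so the
    cluster-specific variant can partition rows by term cluster.
    """

    source_names: tuple[str, ...]
    deltas: np.ndarray
    pair_terms: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.source_names)

    @property
    def n_pairs(self) -> int:
        return self.deltas.shape[0]


def _check_aligned(matrices: list[ScoreMatrix]) -> None:
    ref = matrices[0]
    for sm in matrices[1:]:
        if sm.proteins != ref.proteins or sm.terms != ref.terms:
            raise ValueError(
                f"score matrices {ref.source_name!r} and {sm.source_name!r} have "
                "mismatched protein/term indices"
            )


def average_expression(expr_list: list[ScoreMatrix]) -> ScoreMatrix | None:
    """Element-wise mean over J expression-dataset score matrices (None if J=0)."""
    if not expr_list:
        return None
    _check_aligned(expr_list)
    mean = np.mean([sm.scores for sm in expr_list], axis=0)
    covered = np.any([sm.covered for sm in expr_list], axis=0)
    return ScoreMatrix(
        proteins=list(expr_list[0].proteins), terms=list(expr_list[0].terms),
        scores=mean, source_name="expression", covered=covered,
    )


def average_scores(
    seq: ScoreMatrix | None,
    ppi: ScoreMatrix | None,
    expr_list: list[ScoreMatrix] | None = None,
    renormalize: bool = False,
) -> ScoreMatrix:
    """MS-kNN integration: equal thirds over the three source groups.

    score = 1/3 seq + 1/3 ppi + 1/(3J) sum of the J expression scores. A
    source that does not cover a protein contributes 0 (its score rows are
    already zero), so proteins seen by several sources score higher — the
    deliberate missing-source rule. By default a *whole group* passed as None
    still counts in the denominator (faithful fixed-1/3 mode); with
    ``renormalize=True`` the denominator is the number of groups provided.
    """
    expr = average_expression(list(expr_list) if expr_list else [])
    groups = [g for g in (seq, ppi, expr) if g is not None]
    if not groups:
        raise ValueError("at least one source group is required")
    _check_aligned(groups)
    denom = len(groups) if renormalize else 3
    total = np.sum([g.scores for g in groups], axis=0) / denom
    covered = np.any([g.covered for g in groups], axis=0)
    return ScoreMatrix(
        proteins=list(groups[0].proteins), terms=list(groups[0].terms),
        scores=total, source_name="ms-knn", covered=covered,
    )


def weighted_average(scores: list[ScoreMatrix], wv: WeightVector) -> ScoreMatrix:
    """Entry-wise weighted sum of m aligned score matrices."""
    if len(scores) != len(wv.w):
        raise ValueError(
            f"{len(scores)} score matrices but {len(wv.w)} weights"
        )
    _check_aligned(scores)
    total = np.einsum("j,jpt->pt", wv.w, np.stack([sm.scores for sm in scores]))
    covered = np.any([sm.covered for sm in scores], axis=0)
    return ScoreMatrix(
        proteins=list(scores[0].proteins), terms=list(scores[0].terms),
        scores=total, source_name="weighted", covered=covered,
    )


def build_rank_loss_problem(
    scores: list[ScoreMatrix],
    ann: AnnotationTable,
    max_pairs: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> RankLossProblem:
    """Assemble (positive, negative) term-pair score differences for Eq.-style learning.

    For each training protein, positives are its annotated terms (restricted
    to the score matrices' term set) and negatives are terms annotated in at
    least one *other* training protein but not in this one — absence of an
    annotation is weak evidence, so terms never seen annotated anywhere are
    not used as negatives. The full pair enumeration is quadratic, so pairs
    are uniformly subsampled to ``max_pairs`` with the given seed.
    """
    _check_aligned(scores)
    ref = scores[0]
    rng = np.random.default_rng(rng)
    term_set = set(ref.terms)
    annotated_anywhere = sorted(
        {t for p in ref.proteins for t in ann.terms(p) if t in term_set}
    )
    stack = np.stack([sm.scores for sm in scores])  # m x P x T
    tindex = {t: j for j, t in enumerate(ref.terms)}

    rows: list[np.ndarray] = []
    terms_of_rows: list[str] = []
    for pi, p in enumerate(ref.proteins):
        pos = sorted(ann.terms(p) & term_set)
        if not pos:
            continue
        posset = set(pos)
        neg = [t for t in annotated_anywhere if t not in posset]
        for y in pos:
            fy = stack[:, pi, tindex[y]]
            for ybar in neg:
                rows.append(fy - stack[:, pi, tindex[ybar]])
                terms_of_rows.append(y)
    if not rows:
        raise ValueError("no (positive, negative) term pair exists")
    deltas = np.asarray(rows)
    if len(rows) > max_pairs:
        keep = np.sort(rng.choice(len(rows), size=max_pairs, replace=False))
        deltas = deltas[keep]
        terms_of_rows = [terms_of_rows[i] for i in keep]
        logger.info("subsampled %d of %d rank pairs", max_pairs, len(rows))
    return RankLossProblem(
        source_names=tuple(sm.source_name for sm in scores),
        deltas=deltas,
        pair_terms=tuple(terms_of_rows),
    )


def rank_loss(w: np.ndarray, deltas: np.ndarray) -> float:
    """Total hinge loss sum(max(0, -(deltas @ w))) of weight vector w."""
    return float(np.sum(np.maximum(0.0, -(deltas @ w))))


def _solve_stage(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res


def learn_weights(problem: RankLossProblem) -> WeightVector:
    """Learn simplex weights minimizing the rank hinge loss (linear program).

    The LP's optimum in w is often a face, not a point (e.g. duplicated
    sources give a flat objective). For a deterministic, interpretable
    answer a second stage maximizes, among loss-optimal w, the weight of the
    source with the smallest single-source hinge loss (ties broken by source
    order) — so a perfectly informative source receives weight 1 exactly.
    """
    m = problem.m
    if m == 1:
        wv = np.array([1.0])
        return WeightVector(problem.source_names, wv,
                            objective=rank_loss(wv, problem.deltas))
    D = problem.deltas
    P = D.shape[0]
    # variables: [w_1..w_m, xi_1..xi_P]
    n_var = m + P
    # -(D w) - xi <= 0
    A_ub = np.hstack([-D, -np.eye(P)])
    b_ub = np.zeros(P)
    A_eq = np.zeros((1, n_var))
    A_eq[0, :m] = 1.0
    b_eq = np.array([1.0])
    bounds = [(0, None)] * n_var
    c1 = np.concatenate([np.zeros(m), np.ones(P)])
    res1 = _solve_stage(c1, A_ub, b_ub, A_eq, b_eq, bounds)
    best_loss = float(res1.fun)

    single = [rank_loss(np.eye(m)[j], D) for j in range(m)]
    j_star = int(np.argmin(single))
    # stage 2: maximize w_{j*} subject to total slack <= best_loss
    A_ub2 = np.vstack([A_ub, c1])
    b_ub2 = np.concatenate([b_ub, [best_loss + 1e-9]])
    c2 = np.zeros(n_var)
    c2[j_star] = -1.0
    res2 = _solve_stage(c2, A_ub2, b_ub2, A_eq, b_eq, bounds)
    w = np.clip(res2.x[:m], 0.0, None)
    w = w / w.sum()
    return WeightVector(problem.source_names, w, objective=rank_loss(w, D))


def learn_cluster_weights(
    problem: RankLossProblem, clusters: dict[str, str]
) -> dict[str, WeightVector]:
    """Solve the rank-loss LP independently per term cluster.

    Rows are partitioned by the cluster of their positive term; a cluster
    with no training pairs falls back to uniform weights (logged). Every
    cluster id appearing in ``clusters`` gets a weight vector, so weights can
    be applied to all descendant terms of the cluster.
    """
    missing = {t for t in problem.pair_terms if t not in clusters}
    if missing:
        raise ValueError(f"terms with no cluster id: {sorted(missing)[:5]}")
    pair_clusters = np.array([clusters[t] for t in problem.pair_terms])
    out: dict[str, WeightVector] = {}
    for cid in sorted(set(clusters.values())):
        mask = pair_clusters == cid
        if not mask.any():
            logger.info("cluster %r has no training pairs; uniform fallback", cid)
            out[cid] = WeightVector.uniform(problem.source_names)
            continue
        sub = RankLossProblem(
            source_names=problem.source_names,
            deltas=problem.deltas[mask],
            pair_terms=tuple(t for t, k in zip(problem.pair_terms, mask) if k),
        )
        out[cid] = learn_weights(sub)
    return out


def cluster_weighted_average(
    scores: list[ScoreMatrix],
    weights: dict[str, WeightVector],
    clusters: dict[str, str],
) -> ScoreMatrix:
    """Apply per-cluster weight vectors column-wise (MS-CW-kNN prediction)."""
    _check_aligned(scores)
    ref = scores[0]
    stack = np.stack([sm.scores for sm in scores])  # m x P x T
    total = np.zeros_like(ref.scores)
    for j, t in enumerate(ref.terms):
        wv = weights[clusters[t]]
        total[:, j] = np.einsum("m,mp->p", wv.w, stack[:, :, j])
    covered = np.any([sm.covered for sm in scores], axis=0)
    return ScoreMatrix(
        proteins=list(ref.proteins), terms=list(ref.terms), scores=total,
        source_name="cluster-weighted", covered=covered,
    )
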