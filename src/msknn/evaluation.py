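"""CAFA-style evaluation: term-centric AUC and three protein-centric measures.

Term-centric (TermAUC): for each sufficiently annotated term, rank all test
proteins by their score and compute the ROC AUC against that term's gold
labels (Mann-Whitney rank statistic, ties counted half).

Protein-centric: sweep a score threshold; at each threshold the predicted
set of a protein is the ancestor closure of its above-threshold terms, and
precision/recall are averaged over proteins with at least one prediction.
The Top-N variant keeps each protein's N highest-scoring terms (expanding
ties at the cut) for cutoffs 1..N; the weighted variant counts each term by
its information content -log(frequency) instead of 1, so rare specific terms
dominate. Each measure returns its raw curve plus a trapezoidal area over
the recall-ordered points, so alternative integration conventions can be
recomputed from the curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .knn import ScoreMatrix
from .ontology import AnnotationTable, OntologyDAG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldStandard:
    """Propagated gold annotations of the test proteins, with eligibility cuts.

    ``eligible_terms`` are the terms annotated to more than ``min_count``
    test proteins — term-centric AUC over a handful of positives is noise.
    """

    annotations: AnnotationTable
    eligible_terms: frozenset[str]
    min_count: int

    @classmethod
    def from_annotations(
        cls, ann: AnnotationTable, min_count: int = 25
    ) -> "GoldStandard":
        if not ann.propagated:
            raise ValueError("gold standard requires propagated annotations")
        counts: dict[str, int] = {}
        for ts in ann.assignments.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        eligible = frozenset(t for t, c in counts.items() if c > min_count)
        return cls(annotations=ann, eligible_terms=eligible, min_count=min_count)


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    precision: float
    recall: float


def rank_auc(scores, labels) -> float | None:
    """ROC AUC via the Mann-Whitney rank statistic, ties counted 0.5.

    Returns None ("undefined") when only one class is present; callers
    exclude undefined terms from macro averages.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    pos_rank_sum = float(np.sum(ranks[labels == 1]))
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def term_auc(
    pred: ScoreMatrix, gold: GoldStandard
) -> tuple[dict[str, float | None], float]:
    """Per-eligible-term AUC over all test proteins, plus the macro-average.

    Terms whose AUC is undefined (single-class) are excluded from the macro
    average.
    """
    test_proteins = [p for p in pred.proteins if p in gold.annotations.assignments]
    eligible = sorted(t for t in gold.eligible_terms if t in pred._tindex)
    if not eligible:
        raise ValueError(
            f"no eligible term (min_count={gold.min_count}) is present in the "
            "prediction matrix"
        )
    per_term: dict[str, float | None] = {}
    for t in eligible:
        labels = [1 if t in gold.annotations.terms(p) else 0 for p in test_proteins]
        scores = [pred.score(p, t) for p in test_proteins]
        per_term[t] = rank_auc(scores, labels)
    defined = [a for a in per_term.values() if a is not None]
    if not defined:
        raise ValueError("AUC undefined for every eligible term")
    return per_term, float(np.mean(defined))


def default_thresholds(pred: ScoreMatrix, n: int = 101) -> list[float]:
    """Evenly spaced quantiles of the score distribution (scores are
    unnormalized sums, so a fixed 0-1 grid would collapse)."""
    qs = np.quantile(pred.scores, np.linspace(0.0, 1.0, n))
    return sorted(set(float(q) for q in qs))


def _curve_area(points: list[CurvePoint]) -> float:
    """Trapezoidal area under precision as a function of recall."""
    pr = sorted({(pt.recall, pt.precision) for pt in points})
    if len(pr) < 2:
        return 0.0
    rec = np.array([r for r, _ in pr])
    prec = np.array([p for _, p in pr])
    return float(np.trapezoid(prec, rec))


def _threshold_points(
    pred: ScoreMatrix,
    gold: GoldStandard,
    dag: OntologyDAG,
    thresholds: list[float],
    weight,
) -> list[CurvePoint]:
    test = [p for p in pred.proteins if gold.annotations.terms(p)]
    gold_sets = {p: set(gold.annotations.terms(p)) for p in test}
    points: list[CurvePoint] = []
    for thr in thresholds:
        precisions, recalls = [], []
        for p in test:
            i = pred._pindex[p]
            above = [t for j, t in enumerate(pred.terms) if pred.scores[i, j] > thr]
            if not above:
                continue  # no prediction at this threshold: protein skipped
            predicted = set().union(*(dag.ancestors(t) for t in above))
            g = gold_sets[p]
            tp = sum(weight(t) for t in predicted & g)
            precisions.append(tp / sum(weight(t) for t in predicted))
            recalls.append(tp / sum(weight(t) for t in g))
        if precisions:
            points.append(
                CurvePoint(thr, float(np.mean(precisions)), float(np.mean(recalls)))
            )
    return points


def protein_threshold_curve(
    pred: ScoreMatrix,
    gold: GoldStandard,
    dag: OntologyDAG,
    thresholds: list[float] | None = None,
) -> tuple[list[CurvePoint], float]:
    """Precision/recall sweep with ancestor closure of above-threshold terms."""
    if thresholds is not None and len(thresholds) == 0:
        raise ValueError("empty threshold list")
    thresholds = sorted(thresholds) if thresholds else default_thresholds(pred)
    points = _threshold_points(pred, gold, dag, thresholds, weight=lambda t: 1.0)
    return points, _curve_area(points)


def weighted_threshold_curve(
    pred: ScoreMatrix,
    gold: GoldStandard,
    dag: OntologyDAG,
    ic: dict[str, float],
    thresholds: list[float] | None = None,
) -> tuple[list[CurvePoint], float]:
    """As :func:`protein_threshold_curve` but each term counts by its
    information content, so a wrong rare-term prediction costs more than a
    wrong common-term one. With all-ones IC the two curves coincide."""
    if thresholds is not None and len(thresholds) == 0:
        raise ValueError("empty threshold list")
    needed = set(pred.terms) | set(gold.annotations.annotated_terms())
    missing = {t for t in needed if t not in ic}
    if missing:
        raise ValueError(f"terms with no information content: {sorted(missing)[:5]}")
    thresholds = sorted(thresholds) if thresholds else default_thresholds(pred)
    points = _threshold_points(pred, gold, dag, thresholds, weight=lambda t: ic[t])
    return points, _curve_area(points)


def topn_metric(
    pred: ScoreMatrix, gold: GoldStandard, n: int = 20
) -> tuple[dict[str, tuple[float, float]], list[CurvePoint], float]:
    """Per-protein precision/recall of the top-n scored terms.

    Ties at the n-th score are all retained. Returns the per-protein
    (precision, recall) at cutoff n, the averaged curve over cutoffs 1..n,
    and its trapezoidal area. Proteins whose scores are all zero are skipped
    (and logged): they carry no ranking information.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    test = [p for p in pred.proteins if gold.annotations.terms(p)]
    usable, skipped = [], []
    order_of: dict[str, np.ndarray] = {}
    for p in test:
        row = pred.scores[pred._pindex[p]]
        if np.all(row <= 0):
            skipped.append(p)
            continue
        usable.append(p)
        order_of[p] = np.argsort(-row, kind="stable")
    if skipped:
        logger.info("top-n: skipped %d protein(s) with no nonzero score", len(skipped))

    def retained(p: str, cutoff: int) -> set[str]:
        row = pred.scores[pred._pindex[p]]
        order = order_of[p]
        if cutoff >= len(order):
            return {pred.terms[j] for j in order}
        cut_score = row[order[cutoff - 1]]
        return {pred.terms[j] for j in order if row[j] >= cut_score}

    per_protein: dict[str, tuple[float, float]] = {}
    points: list[CurvePoint] = []
    for cutoff in range(1, n + 1):
        precs, recs = [], []
        for p in usable:
            kept = retained(p, cutoff)
            g = set(gold.annotations.terms(p))
            tp = len(kept & g)
            prec, rec = tp / len(kept), tp / len(g)
            precs.append(prec)
            recs.append(rec)
            if cutoff == n:
                per_protein[p] = (prec, rec)
        if precs:
            points.append(CurvePoint(float(cutoff), float(np.mean(precs)),
                                     float(np.mean(recs))))
    return per_protein, points, _curve_area(points)


def information_content(
    ann: AnnotationTable, epsilon: float = 1e-9
) -> dict[str, float]:
    """IC(f) = -log(frequency of f among annotated proteins in the corpus).

    The corpus must be propagated; terms absent from it get the epsilon-floor
    IC -log(epsilon).
    """
    if not ann.assignments:
        raise ValueError("empty annotation table")
    if not ann.propagated:
        raise ValueError("information content requires a propagated table")
    n = len(ann.assignments)
    counts: dict[str, int] = {}
    for ts in ann.assignments.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n) for t, c in counts.items()}


def ic_for(term: str, ic: dict[str, float], epsilon: float = 1e-9) -> float:
    """IC lookup with the epsilon floor for terms unseen in the corpus."""
    return ic.get(term, -math.log(epsilon))
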