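"""Score integration: plain averaging, LP-learned weights, cluster weights."""

import numpy as np
import pytest

from msknn import (
    AnnotationTable,
    RankLossProblem,
    ScoreMatrix,
    WeightVector,
    average_scores,
    build_rank_loss_problem,
    cluster_weighted_average,
    learn_cluster_weights,
    learn_weights,
    rank_loss,
    weighted_average,
)

# the worked 7-protein example: per-source scores for one term and the
# printed three-way average (expression already aggregated over datasets)
WORKED_EXAMPLE = [
    ("SYK_HUMAN", 0.14, 0.0, 2.17, 0.77),
    ("NOS3_HUMAN", 0.23, 0.0, 1.95, 0.73),
    ("NOS1_HUMAN", 0.29, 0.0, 1.92, 0.74),
    ("OAZ2_HUMAN", 0.17, 0.0, 1.80, 0.66),
    ("OAZ1_HUMAN", 0.18, 0.0, 1.63, 0.60),
    ("PEPD_HUMAN", 0.22, 0.0, 0.0, 0.07),
    ("PON1_HUMAN", 0.26, 1.0, 0.0, 0.42),
]


def matrix(proteins, col, name):
    return ScoreMatrix(
        proteins=proteins, terms=["f"],
        scores=np.array(col, dtype=float).reshape(-1, 1), source_name=name,
    )


def worked_example_matrices():
    proteins = [row[0] for row in WORKED_EXAMPLE]
    expr = matrix(proteins, [row[1] for row in WORKED_EXAMPLE], "expression")
    ppi = matrix(proteins, [row[2] for row in WORKED_EXAMPLE], "ppi")
    seq = matrix(proteins, [row[3] for row in WORKED_EXAMPLE], "sequence")
    return seq, ppi, expr


class TestAverageScores:
    def test_worked_seven_protein_example(self):
        seq, ppi, expr = worked_example_matrices()
        avg = average_scores(seq, ppi, [expr])
        for name, _, _, _, expected in WORKED_EXAMPLE:
            assert round(avg.score(name, "f"), 2) == expected

    def test_all_zero_sources_give_zero(self):
        z = matrix(["p"], [0.0], "x")
        assert average_scores(z, z, [z]).score("p", "f") == 0.0

    def test_expression_datasets_preaveraged(self):
        # J=2 datasets: coefficient is 1/(3J) on their sum
        seq = matrix(["p"], [3.0], "sequence")
        ppi = matrix(["p"], [0.0], "ppi")
        e1 = matrix(["p"], [1.0], "e1")
        e2 = matrix(["p"], [2.0], "e2")
        avg = average_scores(seq, ppi, [e1, e2])
        assert avg.score("p", "f") == pytest.approx(1.0 + (1.0 + 2.0) / 6.0)

    def test_missing_group_fixed_third_by_default(self):
        seq = matrix(["p"], [3.0], "sequence")
        assert average_scores(seq, None, []).score("p", "f") == pytest.approx(1.0)

    def test_missing_group_renormalized_on_request(self):
        seq = matrix(["p"], [3.0], "sequence")
        ppi = matrix(["p"], [1.0], "ppi")
        avg = average_scores(seq, ppi, [], renormalize=True)
        assert avg.score("p", "f") == pytest.approx(2.0)

    def test_index_mismatch_rejected(self):
        a = matrix(["p"], [1.0], "a")
        b = matrix(["q"], [1.0], "b")
        with pytest.raises(ValueError, match="mismatched"):
            average_scores(a, b, [])

    def test_zeroing_a_source_never_raises_score(self):
        # the missing-source rule biases multi-source proteins upward
        rng = np.random.default_rng(17)
        vals = rng.uniform(0, 20, size=(3, 7))
        proteins = [f"p{i}" for i in range(7)]
        full = average_scores(
            matrix(proteins, vals[0], "seq"),
            matrix(proteins, vals[1], "ppi"),
            [matrix(proteins, vals[2], "expr")],
        )
        dropped = average_scores(
            matrix(proteins, vals[0], "seq"),
            matrix(proteins, np.zeros(7), "ppi"),
            [matrix(proteins, vals[2], "expr")],
        )
        assert np.all(full.scores >= dropped.scores - 1e-12)


class TestWeightedAverage:
    def test_unit_weight_returns_source_unchanged(self):
        a = matrix(["p", "q"], [1.0, 2.0], "a")
        b = matrix(["p", "q"], [5.0, 6.0], "b")
        wv = WeightVector(("a", "b"), np.array([1.0, 0.0]))
        np.testing.assert_allclose(weighted_average([a, b], wv).scores, a.scores)

    def test_half_half(self):
        a = matrix(["p"], [2.0], "a")
        b = matrix(["p"], [4.0], "b")
        wv = WeightVector(("a", "b"), np.array([0.5, 0.5]))
        assert weighted_average([a, b], wv).score("p", "f") == pytest.approx(3.0)

    def test_uniform_weights_reproduce_three_way_average(self):
        seq, ppi, expr = worked_example_matrices()
        avg = average_scores(seq, ppi, [expr])
        wv = WeightVector.uniform(("sequence", "ppi", "expression"))
        wavg = weighted_average([seq, ppi, expr], wv)
        np.testing.assert_allclose(wavg.scores, avg.scores, atol=1e-12)

    def test_weight_vector_validation(self):
        with pytest.raises(ValueError):
            WeightVector(("a", "b"), np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            WeightVector(("a", "b"), np.array([1.5, -0.5]))


def grid_search_min(deltas, m, resolution=1e-3):
    """Independent oracle: brute-force the rank loss over a simplex grid."""
    steps = int(round(1 / resolution))
    if m == 1:
        return 1.0, rank_loss(np.array([1.0]), deltas)
    if m == 2:
        w1 = np.arange(steps + 1) / steps
        W = np.stack([w1, 1 - w1], axis=1)
    elif m == 3:
        pts = []
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                pts.append((i / steps, j / steps, (steps - i - j) / steps))
        W = np.array(pts)
    else:
        raise NotImplementedError
    losses = np.maximum(0.0, -(W @ deltas.T)).sum(axis=1)
    best = int(np.argmin(losses))
    return W[best], float(losses[best])


def make_problem(deltas, names=None, terms=None):
    deltas = np.asarray(deltas, dtype=float)
    names = tuple(names or [f"s{j}" for j in range(deltas.shape[1])])
    terms = tuple(terms or ["f"] * deltas.shape[0])
    return RankLossProblem(source_names=names, deltas=deltas, pair_terms=terms)


class TestLearnWeights:
    def test_single_source_trivially_one(self):
        wv = learn_weights(make_problem([[0.5], [-0.2]]))
        assert wv.w[0] == 1.0

    def test_perfect_source_gets_full_weight_zero_objective(self):
        rng = np.random.default_rng(1)
        # source 0 ranks every pair correctly, source 1 reverses every pair
        margins = rng.uniform(0.1, 2.0, size=40)
        deltas = np.stack([margins, -rng.uniform(0.1, 2.0, size=40)], axis=1)
        wv = learn_weights(make_problem(deltas))
        assert wv.objective == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(wv.w, [1.0, 0.0], atol=1e-9)

    def test_duplicated_sources_flat_objective_canonical_vertex(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=30)
        deltas = np.stack([col, col], axis=1)
        problem = make_problem(deltas)
        wv = learn_weights(problem)
        # grid oracle: objective is constant across the simplex
        w_grid = np.arange(0, 1001) / 1000
        losses = [
            rank_loss(np.array([a, 1 - a]), deltas) for a in w_grid[::100]
        ]
        assert np.ptp(losses) < 1e-9
        assert wv.objective == pytest.approx(losses[0], abs=1e-6)
        np.testing.assert_allclose(wv.w, [1.0, 0.0], atol=1e-9)

    @pytest.mark.parametrize("m,seed", [(2, 5), (2, 6), (3, 7)])
    def test_lp_never_beaten_by_grid_search(self, m, seed):
        rng = np.random.default_rng(seed)
        deltas = rng.normal(size=(30, m))
        wv = learn_weights(make_problem(deltas))
        _, grid_best = grid_search_min(deltas, m)
        assert wv.objective <= grid_best + 1e-6

    def test_parameter_recovery_informative_source(self):
        # one signal-bearing source among noise: >= 0.8 of the weight
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n = 60
            signal = rng.uniform(0.2, 1.5, size=n)
            noise1 = rng.normal(scale=1.0, size=n)
            noise2 = rng.normal(scale=1.0, size=n)
            deltas = np.stack([signal, noise1, noise2], axis=1)
            wv = learn_weights(make_problem(deltas))
            assert wv.w[0] >= 0.8


class TestClusterWeights:
    def test_single_cluster_reduces_to_global(self):
        rng = np.random.default_rng(9)
        deltas = rng.normal(size=(25, 2))
        problem = make_problem(deltas)
        global_wv = learn_weights(problem)
        per_cluster = learn_cluster_weights(problem, {"f": "all"})
        np.testing.assert_allclose(per_cluster["all"].w, global_wv.w, atol=1e-9)

    def test_opposite_informative_sources_per_cluster(self):
        rng = np.random.default_rng(10)
        pos = rng.uniform(0.1, 1.0, size=20)
        neg = -rng.uniform(0.1, 1.0, size=20)
        # cluster A: source 0 informative; cluster B: source 1 informative
        deltas = np.vstack(
            [np.stack([pos, neg], axis=1), np.stack([neg, pos], axis=1)]
        )
        terms = ["fa"] * 20 + ["fb"] * 20
        problem = make_problem(deltas, terms=terms)
        wmap = learn_cluster_weights(problem, {"fa": "A", "fb": "B"})
        np.testing.assert_allclose(wmap["A"].w, [1.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(wmap["B"].w, [0.0, 1.0], atol=1e-9)

    def test_empty_cluster_uniform_fallback(self):
        problem = make_problem([[0.5, -0.5]], terms=["fa"])
        wmap = learn_cluster_weights(problem, {"fa": "A", "fb": "B"})
        np.testing.assert_allclose(wmap["B"].w, [0.5, 0.5])

    def test_unclustered_term_rejected(self):
        problem = make_problem([[0.5, -0.5]], terms=["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            learn_cluster_weights(problem, {"fa": "A"})

    def test_cluster_weighted_average_applies_per_column(self):
        a = ScoreMatrix(["p"], ["fa", "fb"], np.array([[2.0, 2.0]]), "a")
        b = ScoreMatrix(["p"], ["fa", "fb"], np.array([[4.0, 4.0]]), "b")
        weights = {
            "A": WeightVector(("a", "b"), np.array([1.0, 0.0])),
            "B": WeightVector(("a", "b"), np.array([0.0, 1.0])),
        }
        out = cluster_weighted_average([a, b], weights, {"fa": "A", "fb": "B"})
        assert out.score("p", "fa") == 2.0
        assert out.score("p", "fb") == 4.0


class TestBuildRankLossProblem:
    def test_pairs_and_features(self):
        ann = AnnotationTable(
            {"p": frozenset({"f1"}), "q": frozenset({"f2"})}, propagated=True
        )
        a = ScoreMatrix(["p", "q"], ["f1", "f2"], np.array([[3.0, 1.0], [0.0, 2.0]]), "a")
        b = ScoreMatrix(["p", "q"], ["f1", "f2"], np.array([[0.5, 0.8], [0.1, 0.2]]), "b")
        problem = build_rank_loss_problem([a, b], ann)
        # p: positive f1 vs negative f2; q: positive f2 vs negative f1
        assert problem.n_pairs == 2
        rows = {tuple(r) for r in np.round(problem.deltas, 9)}
        assert (2.0, -0.3) in rows  # p: f(f1) - f(f2) per source
        assert (2.0, 0.1) in rows   # q: f(f2) - f(f1) per source

    def test_never_annotated_terms_not_used_as_negatives(self):
        ann = AnnotationTable({"p": frozenset({"f1"})}, propagated=True)
        a = ScoreMatrix(["p"], ["f1", "f_unseen"], np.array([[3.0, 1.0]]), "a")
        with pytest.raises(ValueError, match="no .* pair"):
            build_rank_loss_problem([a], ann)

    def test_subsampling_is_seeded_and_capped(self):
        rng = np.random.default_rng(0)
        terms = [f"f{i}" for i in range(12)]
        proteins = [f"p{i}" for i in range(10)]
        scores = rng.uniform(size=(10, 12))
        ann = AnnotationTable(
            {p: frozenset(rng.choice(terms, size=3, replace=False))
             for p in proteins},
            propagated=True,
        )
        a = ScoreMatrix(proteins, terms, scores, "a")
        p1 = build_rank_loss_problem([a], ann, max_pairs=50, rng=4)
        p2 = build_rank_loss_problem([a], ann, max_pairs=50, rng=4)
        assert p1.n_pairs == 50
        np.testing.assert_array_equal(p1.deltas, p2.deltas)
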