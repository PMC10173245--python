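"""Fidelity measures: identity cases, arithmetic oracles, simulations."""

import math

import numpy as np
import pytest

from grandpa.core import GenerationSpec, LabelDimension, LabelSchema, PropertyGraph
from grandpa.evaluation import (
    CcdfCurve,
    DegenerateFitError,
    community_agreement,
    degree_ccdf,
    eigenvector_centralities,
    evaluate,
    homophily_odds_ratio,
    joint_probability_residuals,
    ks_two_sample,
    match_vertices,
    nrmse_ccdf,
)
from grandpa.fixtures import homophily_testbed
from grandpa.generation import grandpa_generate

from conftest import graph_from


class TestDegreeCcdf:
    def test_triangle(self, triangle_ab):
        curve = degree_ccdf(triangle_ab)
        assert curve.values.tolist() == [1.0, 1.0, 0.0]

    def test_isolated_vertex(self):
        g = graph_from([], {"a": ("X",)})
        assert degree_ccdf(g).values.tolist() == [0.0]

    def test_karate_matches_counting_oracle(self, karate):
        curve = degree_ccdf(karate)
        degs = sorted(karate.degrees().values())
        for k, val in enumerate(curve.values):
            assert val == pytest.approx(sum(d > k for d in degs) / 34)

    def test_monotone_invariant_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CcdfCurve(np.arange(3), np.array([0.1, 0.5, 0.0]))


class TestNrmse:
    def test_identity_is_zero(self, karate):
        c = degree_ccdf(karate)
        assert nrmse_ccdf(c, c) == 0.0

    def test_hand_computed_example(self):
        a = CcdfCurve(np.arange(2), np.array([1.0, 0.0]))
        b = CcdfCurve(np.arange(3), np.array([1.0, 1.0, 0.0]))
        # union support length 3; a extends to [1,0,0]; diffs (0,1,0)
        assert nrmse_ccdf(a, b) == pytest.approx(math.sqrt(1 / 3))

    def test_constant_source_curve_rejected(self):
        a = CcdfCurve(np.arange(2), np.array([1.0, 1.0]))
        b = CcdfCurve(np.arange(2), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            nrmse_ccdf(a, b)


class TestKs:
    def test_identical_samples(self):
        stat, p = ks_two_sample([1, 2, 3, 3], [1, 2, 3, 3])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_two_sample([0, 0], [5, 5])
        assert stat == 1.0

    def test_null_rejection_rate_calibrated(self):
        # two samples from one distribution: ~5% rejections at alpha=.05
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.normal(size=500)
            y = rng.normal(size=500)
            _, p = ks_two_sample(x, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestEigenvectorCentrality:
    def test_matches_dense_eigendecomposition(self, karate):
        ours = eigenvector_centralities(karate)
        order = list(karate.vertices)
        idx = {v: i for i, v in enumerate(order)}
        A = np.zeros((34, 34))
        for u, v in karate.edges:
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
        w, vecs = np.linalg.eigh(A)
        principal = np.abs(vecs[:, np.argmax(w)])
        principal /= np.linalg.norm(principal)
        for v in order:
            assert ours[v] == pytest.approx(principal[idx[v]], abs=1e-6)


class TestMatching:
    def _relabelled_copy(self, graph, prefix="n"):
        rename = {v: f"{prefix}{v}" for v in graph.vertices}
        return PropertyGraph(
            [rename[v] for v in graph.vertices],
            [(rename[u], rename[v]) for u, v in graph.edges],
            {rename[v]: graph.labels[v] for v in graph.vertices},
            graph.schema,
        )

    def test_relabelled_copy_matches_perfectly(self, karate_labeled):
        gen = self._relabelled_copy(karate_labeled)
        matching = match_vertices(karate_labeled, gen)
        assert len(matching) == 34
        for s, g in matching.items():
            assert karate_labeled.labels[s] == gen.labels[g]
            assert karate_labeled.degree(s) == gen.degree(g)

    def test_unmatched_when_category_absent(self):
        src = graph_from([("a", "b")], {"a": ("X",), "b": ("Y",)})
        gen = graph_from([("p", "q")], {"p": ("X",), "q": ("Z",)})
        matching = match_vertices(src, gen)
        assert "b" not in matching
        assert matching == {"a": "p"}

    def test_small_pair_matches_minimal_cost_assignment(self):
        # one shared category, structural distances decide; with distinct
        # degrees the greedy order equals the optimal assignment
        src = graph_from(
            [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")],
            {v: ("X",) for v in "abcd"},
        )
        gen = self._relabelled_copy(src)
        matching = match_vertices(src, gen)
        from scipy.optimize import linear_sum_assignment

        s_deg = src.degrees()
        g_deg = gen.degrees()
        svs, gvs = sorted(src.vertices), sorted(gen.vertices)
        cost = np.array([[abs(s_deg[s] - g_deg[g]) for g in gvs] for s in svs])
        rows, cols = linear_sum_assignment(cost)
        optimal_cost = cost[rows, cols].sum()
        ours_cost = sum(abs(s_deg[s] - g_deg[g]) for s, g in matching.items())
        assert ours_cost == optimal_cost == 0


def _with_communities(assignments: dict[str, str], edges=()) -> PropertyGraph:
    dim = LabelDimension("community", tuple(set(assignments.values())), "community")
    return PropertyGraph(
        assignments.keys(),
        edges,
        {v: (c,) for v, c in assignments.items()},
        LabelSchema((dim,)),
    )


class TestCommunityAgreement:
    def test_identity(self):
        src = _with_communities({f"v{i}": f"c{i % 3 + 1}" for i in range(12)})
        matching = {v: v for v in src.vertices}
        assert community_agreement(src, src, matching) == 1.0

    def test_pure_relabelling_scores_one(self):
        assign = {f"v{i}": f"c{i % 3 + 1}" for i in range(12)}
        permuted = {v: {"c1": "c3", "c2": "c1", "c3": "c2"}[c] for v, c in assign.items()}
        src = _with_communities(assign)
        gen = _with_communities(permuted)
        matching = {v: v for v in src.vertices}
        assert community_agreement(src, gen, matching) == 1.0

    def test_known_noise_level_recovered(self):
        # flip exactly 10 of 100 memberships: agreement must be 0.90
        rng = np.random.default_rng(0)
        assign = {f"v{i}": f"c{i % 5 + 1}" for i in range(100)}
        noisy = dict(assign)
        flipped = rng.choice(100, size=10, replace=False)
        for i in flipped:
            v = f"v{i}"
            noisy[v] = f"c{(int(assign[v][1]) % 5) + 1}"
        src = _with_communities(assign)
        gen = _with_communities(noisy)
        matching = {v: v for v in src.vertices}
        assert community_agreement(src, gen, matching) == pytest.approx(0.90)

    def test_missing_dimension_rejected(self, triangle_ab):
        with pytest.raises(ValueError, match="community"):
            community_agreement(triangle_ab, triangle_ab, {})


class TestJointResiduals:
    def test_identity_is_zero(self, karate_labeled):
        assert joint_probability_residuals(karate_labeled, karate_labeled) == (0.0, 0.0)

    def test_hand_summed_edge_residual(self):
        src = graph_from(
            [("x", "y"), ("y", "z"), ("x", "z")],
            {"x": ("A",), "y": ("A",), "z": ("B",)},
        )
        gen = graph_from(
            [("p", "q")], {"p": ("A",), "q": ("B",), "r": ("A",)}
        )
        vssr, essr = joint_probability_residuals(src, gen)
        assert vssr == pytest.approx(0.0)
        # src pairs: {A,A}:1/3, {A,B}:2/3; gen pairs: {A,B}:1
        assert essr == pytest.approx((1 / 3) ** 2 + (2 / 3 - 1) ** 2)

    def test_projects_onto_shared_dimensions(self, karate_labeled):
        from grandpa.augmentation import BinningScheme, degree_bin_labels

        augmented = degree_bin_labels(karate_labeled, BinningScheme("quantile", n_b=3))
        vssr, essr = joint_probability_residuals(karate_labeled, augmented)
        assert vssr == 0.0 and essr == 0.0


class TestHomophilyRegression:
    def test_one_sided_outcome_rejected(self):
        g = graph_from([("a", "b")], {"a": ("T",), "b": ("T",)})
        with pytest.raises(DegenerateFitError):
            homophily_odds_ratio(g, "d0", {"T"})

    def test_constant_predictor_rejected(self):
        g = graph_from(
            [("a", "b"), ("c", "d")],
            {"a": ("T",), "b": ("T",), "c": ("U",), "d": ("U",)},
        )
        with pytest.raises(DegenerateFitError):
            homophily_odds_ratio(g, "d0", {"T"})

    def test_known_slope_recovered_within_three_se(self):
        g, true_or = homophily_testbed(n_stars=500, seed=11)
        fit = homophily_odds_ratio(g, "specialty", {"T"})
        assert abs(fit.slope - math.log(true_or)) < 3 * fit.slope_se

    def test_null_slope_ci_covers_one(self):
        # independent outcome and predictor: CI should usually cover OR=1
        covered = 0
        for seed in range(40):
            g, _ = homophily_testbed(n_stars=300, intercept=math.log(0.25),
                                     slope=0.0, seed=seed)
            fit = homophily_odds_ratio(g, "specialty", {"T"})
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered >= 33  # ~95% nominal, allow sampling slack


class TestEvaluate:
    def test_self_comparison_is_perfect(self, karate_labeled):
        rep = evaluate(karate_labeled, karate_labeled,
                       community_method="edge_betweenness")
        assert rep.nrmse_degree == 0.0
        assert rep.ks_degree[0] == 0.0
        assert rep.community_agreement == 1.0
        assert rep.vertex_ssr == 0.0 and rep.edge_ssr == 0.0
        assert rep.community_count_source == rep.community_count_generated

    def test_report_composes_individual_measures(self, karate_labeled):
        from grandpa.augmentation import BinningScheme
        from grandpa.generation import CommunityAugmentation, DegreeAugmentation

        res = grandpa_generate(
            karate_labeled,
            GenerationSpec(34, 78, seed=4, tolerance=0.0, max_iterations=5),
            [
                CommunityAugmentation("edge_betweenness"),
                DegreeAugmentation(BinningScheme("quantile", n_b=10)),
            ],
        )
        rep = evaluate(res.augmented_source, res.graph,
                       community_method="edge_betweenness")
        assert rep.nrmse_degree == pytest.approx(res.final_error)
        vssr, essr = joint_probability_residuals(res.augmented_source, res.graph)
        assert rep.vertex_ssr == pytest.approx(vssr)
        assert rep.edge_ssr == pytest.approx(essr)
        assert rep.to_row().shape[0] == 1

    def test_json_round_trip(self, karate_labeled):
        import json

        rep = evaluate(karate_labeled, karate_labeled,
                       community_method="edge_betweenness")
        payload = json.loads(rep.to_json())
        assert payload["community_agreement"] == 1.0
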