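"""The six baseline centralities: hand values, symmetry, oracles."""

import itertools
import math

import numpy as np
import pytest

from spreadrank import (
    all_pairs_distances,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    fixture,
    gravity,
    weighted_gravity,
)
from spreadrank.baselines import gravity_interaction_matrix
from conftest import random_graph

ALL_METHODS = [
    degree_centrality,
    betweenness_centrality,
    closeness_centrality,
    eigenvector_centrality,
    gravity,
    weighted_gravity,
]


def betweenness_oracle(graph):
    """Exhaustive shortest-path enumeration, summed over unordered pairs."""
    import networkx as nx

    g = graph.to_networkx()
    scores = {lab: 0.0 for lab in graph.labels}
    for m, n in itertools.combinations(graph.labels, 2):
        if not nx.has_path(g, m, n):
            continue
        paths = list(nx.all_simple_paths(g, m, n))
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for i in graph.labels:
            if i in (m, n):
                continue
            through = sum(1 for p in geodesics if i in p[1:-1])
            scores[i] += through / len(geodesics)
    return scores


class TestDegreeAndBetweenness:
    def test_degree_scores(self, star4, cycle5):
        assert degree_centrality(star4).scores["s"] == 3
        assert set(degree_centrality(cycle5).scores.values()) == {2}

    def test_degree_empty_graph(self):
        from spreadrank import Graph

        scores = degree_centrality(Graph(("a", "b"), [])).scores
        assert set(scores.values()) == {0}

    def test_betweenness_path_and_star(self, path3, star4):
        b = betweenness_centrality(path3).scores
        assert b["b"] == 1 and b["a"] == 0
        assert betweenness_centrality(star4).scores["s"] == 3  # 3 leaf pairs

    def test_betweenness_complete_graph_zero(self, complete5):
        assert set(betweenness_centrality(complete5).scores.values()) == {0}

    @pytest.mark.parametrize("seed", range(8))
    def test_betweenness_matches_enumeration_oracle(self, seed):
        g = random_graph(seed, n=7, p=0.4)
        got = betweenness_centrality(g).scores
        want = betweenness_oracle(g)
        for lab in g.labels:
            assert got[lab] == pytest.approx(want[lab], abs=1e-12)


class TestCloseness:
    def test_classic_hand_values(self, path3, complete5):
        cc = closeness_centrality(path3).scores
        assert cc["b"] == pytest.approx(1.0)
        assert cc["a"] == pytest.approx(2 / 3)
        assert set(closeness_centrality(complete5).scores.values()) == {1.0}

    def test_classic_rejects_disconnected(self):
        from spreadrank import Graph

        g = Graph.from_edges([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="harmonic"):
            closeness_centrality(g)

    def test_harmonic_on_disconnected(self):
        from spreadrank import Graph

        g = Graph.from_edges([("a", "b"), ("c", "d")])
        scores = closeness_centrality(g, variant="harmonic").scores
        assert scores["a"] == 1.0  # the unreachable pair contributes 0

    def test_unknown_variant(self, path3):
        with pytest.raises(ValueError, match="variant"):
            closeness_centrality(path3, variant="bogus")


class TestEigenvector:
    def test_complete_graph_uniform(self, complete5):
        scores = eigenvector_centrality(complete5).scores
        for v in scores.values():
            assert v == pytest.approx(1 / math.sqrt(5), abs=1e-8)

    @pytest.mark.parametrize("leaves", [3, 6, 10])
    def test_star_center_leaf_ratio_sqrt_l(self, leaves):
        from spreadrank import Graph

        labels = ("hub",) + tuple(f"l{i}" for i in range(leaves))
        g = Graph(labels, [("hub", lab) for lab in labels[1:]])
        res = eigenvector_centrality(g)
        ratio = res.scores["hub"] / res.scores["l0"]
        assert ratio == pytest.approx(math.sqrt(leaves), abs=1e-8)
        assert res.eigenvalue == pytest.approx(math.sqrt(leaves), abs=1e-8)

    def test_matches_dense_eigensolver(self):
        g = random_graph(3, n=12, p=0.3)
        res = eigenvector_centrality(g)
        a = g.adjacency_matrix().astype(float)
        w, v = np.linalg.eigh(a)
        principal = np.abs(v[:, np.argmax(w)])
        got = np.array([res.scores[lab] for lab in g.labels])
        assert np.allclose(got, principal, atol=1e-7)
        assert res.eigenvalue == pytest.approx(w.max(), abs=1e-7)

    def test_unit_norm_nonnegative(self):
        g = random_graph(5, n=15, p=0.25)
        scores = np.array(list(eigenvector_centrality(g).scores.values()))
        assert (scores >= 0).all()
        assert np.linalg.norm(scores) == pytest.approx(1.0, abs=1e-9)

    def test_requires_an_edge(self):
        from spreadrank import Graph

        with pytest.raises(ValueError, match="edge"):
            eigenvector_centrality(Graph(("a", "b"), []))

    def test_iteration_budget_error(self, path3):
        with pytest.raises(RuntimeError, match="converge"):
            eigenvector_centrality(path3, tol=0.0, max_iter=5)


class TestGravity:
    def test_path3_hand_values(self, path3):
        cg = gravity(path3).scores
        assert cg["b"] == pytest.approx(4.0)       # 2*1/1 + 2*1/1
        assert cg["a"] == pytest.approx(2.25)      # 1*2/1 + 1*1/4

    def test_star4_hand_values(self, star4):
        cg = gravity(star4).scores
        assert cg["s"] == pytest.approx(9.0)       # 3 * (3*1/1)
        assert cg["a"] == pytest.approx(3.5)       # 3/1 + 2 * 1/4

    def test_edgeless_graph_all_zero(self):
        from spreadrank import Graph

        assert set(gravity(Graph(("a", "b"), [])).scores.values()) == {0.0}

    def test_unreachable_pairs_contribute_zero(self):
        from spreadrank import Graph

        g = Graph.from_edges([("a", "b"), ("c", "d")])
        assert gravity(g).scores["a"] == pytest.approx(1.0)

    def test_interaction_matrix_symmetric(self):
        g = random_graph(11, n=12, p=0.3)
        mat = gravity_interaction_matrix(g)
        assert np.array_equal(mat, mat.T)
        assert (np.diag(mat) == 0).all()

    def test_accepts_precomputed_distances(self, path3):
        d = all_pairs_distances(path3)
        assert gravity(path3, d).scores == gravity(path3).scores


class TestWeightedGravity:
    def test_complete_graph_uniform(self, complete5):
        assert len(set(weighted_gravity(complete5).scores.values())) == 1

    def test_path_mirror_symmetry(self, path3):
        wg = weighted_gravity(path3).scores
        assert wg["a"] == pytest.approx(wg["c"], rel=1e-9)

    def test_star_center_first(self, star4):
        wg = weighted_gravity(star4)
        assert wg.ranking()[0] == "s"

    def test_is_eigenvector_times_gravity(self, star4):
        wg = weighted_gravity(star4).scores
        ec = eigenvector_centrality(star4).scores
        cg = gravity(star4).scores
        for lab in star4.labels:
            assert wg[lab] == pytest.approx(ec[lab] * cg[lab], rel=1e-12)


class TestStructuralSymmetry:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_vertex_transitive_graphs_constant(self, method, cycle5, complete5):
        for g in (cycle5, complete5):
            scores = np.array(list(method(g).scores.values()))
            assert np.allclose(scores, scores[0], atol=1e-9)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_two_stars_bridge_mirror_pairs_tie(self, method, two_stars_bridge):
        s = method(two_stars_bridge).scores
        assert s["h1"] == pytest.approx(s["h2"], rel=1e-9)
        assert s["a1"] == pytest.approx(s["b1"], rel=1e-9)
        assert s["a1"] == pytest.approx(s["a2"], rel=1e-9)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_star_center_is_unique_argmax(self, method, star4):
        s = method(star4).scores
        assert all(s["s"] > s[leaf] for leaf in ("a", "b", "c"))
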