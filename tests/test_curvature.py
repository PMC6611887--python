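"""Neighborhood measures, W1, and edge curvature."""

import networkx as nx
import numpy as np
import pytest

from orclust import (
    affected_edges,
    compute_all_curvatures,
    edge_curvature,
    neighborhood_measure,
    wasserstein1,
)
from orclust.graph import distances_between

from conftest import random_connected_graph
from oracles import lp_curvature, w1_uniform_assignment


class TestNeighborhoodMeasure:
    def test_uniform_on_unweighted(self):
        g = nx.star_graph(3)  # hub 0, leaves 1..3
        mu = neighborhood_measure(g, 0)
        assert mu.support == (1, 2, 3)
        assert np.allclose(mu.masses, 1 / 3)

    def test_weight_proportional(self):
        g = nx.Graph()
        g.add_edge("i", "a", weight=2.0)
        g.add_edge("i", "b", weight=1.0)
        g.add_edge("i", "c", weight=1.0)
        mu = neighborhood_measure(g, "i")
        assert mu.as_dict() == {"a": 0.5, "b": 0.25, "c": 0.25}

    def test_leaf_is_point_mass(self):
        g = nx.path_graph(2)
        mu = neighborhood_measure(g, 0)
        assert mu.as_dict() == {1: 1.0}

    def test_isolated_vertex_rejected(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(ValueError, match="isolated"):
            neighborhood_measure(g, "x")


class TestWasserstein:
    def test_triangle_half(self, triangle):
        # K3 edge (0,1): mu_0 = 1/2 on {1,2}, mu_1 = 1/2 on {0,2};
        # brute force over 2x2 plans gives W1 = 1/2
        mu0 = neighborhood_measure(triangle, 0)
        mu1 = neighborhood_measure(triangle, 1)
        d = distances_between(triangle, triangle.nodes(), triangle.nodes())
        plan = wasserstein1(mu0, mu1, d)
        assert plan.cost == pytest.approx(0.5)
        assert np.allclose(plan.matrix.sum(axis=1), mu0.masses)
        assert np.allclose(plan.matrix.sum(axis=0), mu1.masses)

    def test_four_cycle_one(self):
        g = nx.cycle_graph(4)
        mu0 = neighborhood_measure(g, 0)
        mu1 = neighborhood_measure(g, 1)
        d = distances_between(g, g.nodes(), g.nodes())
        assert wasserstein1(mu0, mu1, d).cost == pytest.approx(1.0)

    def test_identical_measures_zero(self):
        g = nx.Graph()
        # u and v see the same two neighbors with the same weights
        g.add_edges_from([("u", "a"), ("u", "b"), ("v", "a"), ("v", "b")])
        mu_u = neighborhood_measure(g, "u")
        mu_v = neighborhood_measure(g, "v")
        d = distances_between(g, g.nodes(), g.nodes())
        assert wasserstein1(mu_u, mu_v, d).cost == pytest.approx(0.0)

    def test_symmetry_on_random_graphs(self, rng):
        for _ in range(25):
            g = random_connected_graph(rng)
            d = distances_between(g, g.nodes(), g.nodes())
            u, v = sorted(g.edges())[0]
            mu_u = neighborhood_measure(g, u)
            mu_v = neighborhood_measure(g, v)
            assert wasserstein1(mu_u, mu_v, d).cost == pytest.approx(
                wasserstein1(mu_v, mu_u, d).cost, abs=1e-9
            )

    def test_disconnected_support_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_edge("c", "d")
        mu_a = neighborhood_measure(g, "a")
        mu_c = neighborhood_measure(g, "c")
        d = distances_between(g, g.nodes(), g.nodes())
        with pytest.raises(ValueError, match="disconnected"):
            wasserstein1(mu_a, mu_c, d)


class TestEdgeCurvature:
    def test_leaf_edges_zero(self):
        # a degree-1 endpoint forces kappa = 0 on unweighted graphs
        for g, e in [
            (nx.star_graph(4), (0, 1)),
            (nx.path_graph(5), (0, 1)),
            (nx.lollipop_graph(4, 2), (4, 5)),
        ]:
            assert edge_curvature(g, e) == 0.0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_closed_form(self, n):
        g = nx.complete_graph(n)
        k = edge_curvature(g, (0, 1))
        assert k == pytest.approx((n - 2) / (n - 1), abs=1e-9)

    def test_binary_tree_interior(self):
        g = nx.balanced_tree(2, 3)
        # both endpoints of (1, 3) have degree 3
        assert edge_curvature(g, (1, 3)) == pytest.approx(-2 / 3, abs=1e-9)

    def test_path_interior_zero(self):
        g = nx.path_graph(6)
        for e in [(1, 2), (2, 3), (3, 4)]:
            assert edge_curvature(g, e) == 0.0

    def test_tree_closed_form_vs_lp(self, rng, random_tree_deg3):
        """kappa = -2(1 - 1/deg_i - 1/deg_j) on interior tree edges."""
        g = random_tree_deg3(rng)
        checked = 0
        for u, v in g.edges():
            if g.degree(u) >= 2 and g.degree(v) >= 2:
                expect = -2 * (1 - 1 / g.degree(u) - 1 / g.degree(v))
                assert edge_curvature(g, (u, v)) == pytest.approx(expect, abs=1e-9)
                assert lp_curvature(g, u, v) == pytest.approx(expect, abs=1e-9)
                checked += 1
        assert checked >= 3

    def test_bounds_on_random_unweighted_graphs(self, rng):
        for _ in range(15):
            g = random_connected_graph(rng)
            table = compute_all_curvatures(g)
            for _, k in table.items():
                assert -2 - 1e-9 <= k <= 1 + 1e-9

    def test_matches_lp_reference_on_random_graphs(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng)
            table = compute_all_curvatures(g)
            for (u, v), k in table.items():
                assert k == pytest.approx(lp_curvature(g, u, v), abs=1e-8)

    def test_matches_assignment_oracle_on_weights(self):
        g = nx.Graph()
        for x, y, w in [("a", "b", 2.0), ("b", "c", 1.0), ("c", "a", 1.0), ("c", "d", 3.0)]:
            g.add_edge(x, y, weight=w)
        table = compute_all_curvatures(g)
        for (u, v), k in table.items():
            assert k == pytest.approx(lp_curvature(g, u, v), abs=1e-9)


class TestCurvatureTable:
    def test_k5_table(self):
        table = compute_all_curvatures(nx.complete_graph(5))
        assert len(table) == 10
        assert np.allclose(table.values(), 0.75)

    def test_path_all_zero(self):
        table = compute_all_curvatures(nx.path_graph(5))
        assert np.allclose(table.values(), 0.0)

    def test_barbell_bridge_uniquely_most_negative(self, barbell):
        table = compute_all_curvatures(barbell)
        (u, v), k = table.min()
        assert (u, v) == (4, 5)
        assert k < 0
        others = [kk for e, kk in table.items() if e != (4, 5)]
        assert min(others) > k

    def test_determinism(self, rng):
        g = random_connected_graph(rng)
        t1 = compute_all_curvatures(g)
        t2 = compute_all_curvatures(g)
        assert t1.items() == t2.items()

    def test_tsv_dump(self, tmp_path, triangle):
        table = compute_all_curvatures(triangle)
        p = tmp_path / "k.tsv"
        table.to_tsv(str(p))
        lines = p.read_text().strip().split("\n")
        assert lines[0] == "u\tv\tkappa"
        assert len(lines) == 4

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            compute_all_curvatures(nx.empty_graph(3))


class TestAffectedEdges:
    def test_k3_removal_touches_both_survivors(self, triangle):
        h = triangle.copy()
        h.remove_edge(0, 1)
        assert affected_edges(h, (0, 1), mode="local") == {(0, 2), (1, 2)}

    def test_barbell_bridge_removal_touches_both_cliques(self, barbell):
        table = compute_all_curvatures(barbell)
        h = barbell.copy()
        h.remove_edge(4, 5)
        local = affected_edges(h, (4, 5), mode="local")
        assert local == set(map(tuple, map(sorted, h.edges())))
        exact = affected_edges(h, (4, 5), mode="exact", table=table)
        assert exact <= local

    def test_local_misses_distance_mediated_change(self):
        """A weighted 6-cycle where an edge outside the 2-hop zone of the
        removal changes curvature: exact mode sees it, local does not."""
        g = nx.Graph()
        for x, y, w in [
            ("u", "v", 1.0), ("k", "u", 1.0), ("v", "l", 1.0),
            ("a", "k", 5.0), ("b", "l", 5.0), ("a", "b", 1.0),
        ]:
            g.add_edge(x, y, weight=w)
        table = compute_all_curvatures(g)
        h = g.copy()
        h.remove_edge("u", "v")
        local = affected_edges(h, ("u", "v"), mode="local")
        exact = affected_edges(h, ("u", "v"), mode="exact", table=table)
        assert ("a", "b") in exact
        assert ("a", "b") not in local

    def test_exact_mode_needs_table(self, triangle):
        h = triangle.copy()
        h.remove_edge(0, 1)
        with pytest.raises(ValueError, match="table"):
            affected_edges(h, (0, 1), mode="exact")


def test_uniform_w1_matches_assignment_oracle(rng):
    """Engine W1 equals the Hungarian unit-replication oracle on neighborhoods."""
    from orclust._transport import solve_transport
    from oracles import floyd_warshall

    for _ in range(30):
        g = random_connected_graph(rng)
        d = floyd_warshall(g)
        u, v = sorted(g.edges())[0]
        nu = sorted(g.neighbors(u))
        nv = sorted(g.neighbors(v))
        C = np.array([[d[(x, y)] for y in nv] for x in nu], dtype=float)
        a = np.full(len(nu), 1 / len(nu))
        b = np.full(len(nv), 1 / len(nv))
        _, w1 = solve_transport(a, b, C)
        assert w1 == pytest.approx(w1_uniform_assignment(C), abs=1e-9)
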