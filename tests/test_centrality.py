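import itertools

import numpy as np
import pytest

from symptomnet import (
    betweenness_centrality,
    degree_centrality,
    eigenvector_centrality,
    summary_table,
)


def random_network(rng, n_nodes, p_edge, builder):
    nodes = [f"N{k}" for k in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                r = rng.uniform(0.1, 0.9) * rng.choice([-1, 1])
                edges.append((nodes[i], nodes[j], r))
    return builder(nodes, edges)


def brute_force_betweenness(net):
    """Exhaustive shortest-path enumeration (BFS level sets + path counting
    by DFS), independent of the Brandes-based implementation."""
    nodes = net.nodes
    adj = {n: set() for n in nodes}
    for e in net.edges:
        adj[e.pair[0]].add(e.pair[1])
        adj[e.pair[1]].add(e.pair[0])

    def all_shortest_paths(s, t):
        # BFS distances from s, then enumerate paths that descend distance
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    score = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for interior in p[1:-1]:
                score[interior] += 1.0 / len(paths)
    return score


def brute_force_eigenvector(net):
    """Dense eigendecomposition of the absolute-weight adjacency."""
    A = net.adjacency(absolute=True)
    w, V = np.linalg.eigh(A)
    v = V[:, np.argmax(w)]
    v = np.abs(v)
    return v / v.max()


class TestDegree:
    def test_empty_network_all_zero(self, net_builder):
        net = net_builder(["a", "b", "c"], [])
        deg = degree_centrality(net)
        assert (deg == 0).all().all()

    def test_sign_split(self, net_builder):
        # hub with 5 positive and 2 negative incident edges has degree 7
        leaves = [f"l{k}" for k in range(7)]
        rs = [0.3] * 5 + [-0.3] * 2
        net = net_builder(["hub"] + leaves,
                          [("hub", l, r) for l, r in zip(leaves, rs)])
        deg = degree_centrality(net)
        assert deg.loc["hub", "degree"] == 7
        assert deg.loc["hub", "positive"] == 5
        assert deg.loc["hub", "negative"] == 2

    def test_star_graph(self, net_builder):
        leaves = [f"l{k}" for k in range(6)]
        net = net_builder(["c"] + leaves, [("c", l, 0.4) for l in leaves])
        deg = degree_centrality(net)
        assert deg.loc["c", "degree"] == 6
        assert (deg.loc[leaves, "degree"] == 1).all()

    def test_degree_equals_sign_split_sum(self, net_builder):
        rng = np.random.default_rng(0)
        net = random_network(rng, 10, 0.4, net_builder)
        deg = degree_centrality(net)
        assert (deg["degree"] == deg["positive"] + deg["negative"]).all()


class TestEigenvector:
    def test_single_edge_symmetric(self, net_builder):
        net = net_builder(["a", "b", "c"], [("a", "b", 0.5)])
        eig = eigenvector_centrality(net)
        assert eig["a"] == pytest.approx(1.0)
        assert eig["b"] == pytest.approx(1.0)
        assert eig["c"] == 0.0

    def test_star_leaf_ratio(self, net_builder):
        # leading eigenvector of the k-star: leaf / center = 1 / sqrt(k)
        leaves = [f"l{k}" for k in range(4)]
        net = net_builder(["c"] + leaves, [("c", l, 0.3) for l in leaves])
        eig = eigenvector_centrality(net)
        assert eig["c"] == pytest.approx(1.0)
        for l in leaves:
            assert eig[l] == pytest.approx(0.5, abs=1e-9)

    def test_invariant_under_global_weight_rescale(self, net_builder):
        rng = np.random.default_rng(1)
        nodes = [f"N{k}" for k in range(8)]
        edges = [(nodes[i], nodes[j], rng.uniform(0.05, 0.2))
                 for i in range(8) for j in range(i + 1, 8) if rng.random() < 0.5]
        a = eigenvector_centrality(net_builder(nodes, edges))
        b = eigenvector_centrality(
            net_builder(nodes, [(x, y, 3.7 * r) for x, y, r in edges]))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_matches_dense_eigendecomposition(self, net_builder):
        rng = np.random.default_rng(3)
        for _ in range(30):
            net = random_network(rng, int(rng.integers(3, 9)), 0.5, net_builder)
            if net.n_edges == 0:
                continue
            impl = eigenvector_centrality(net).to_numpy()
            oracle = brute_force_eigenvector(net)
            assert np.abs(impl - oracle).max() < 1e-8

    def test_edgeless_network_is_an_error(self, net_builder):
        with pytest.raises(ValueError):
            eigenvector_centrality(net_builder(["a", "b"], []))


class TestBetweenness:
    def test_path_center(self, net_builder):
        net = net_builder(["a", "b", "c"], [("a", "b", 0.3), ("b", "c", 0.3)])
        bet = betweenness_centrality(net)
        assert bet["b"] == 1.0
        assert bet["a"] == bet["c"] == 0.0

    def test_four_cycle_tied_paths(self, net_builder):
        nodes = ["a", "b", "c", "d"]
        net = net_builder(nodes, [("a", "b", 0.3), ("b", "c", 0.3),
                                  ("c", "d", 0.3), ("d", "a", 0.3)])
        bet = betweenness_centrality(net)
        # each opposite pair has two tied shortest paths, half credit each
        assert all(bet[n] == pytest.approx(0.5) for n in nodes)

    def test_matches_exhaustive_enumeration(self, net_builder):
        rng = np.random.default_rng(4)
        for _ in range(50):
            net = random_network(rng, int(rng.integers(2, 7)), 0.5, net_builder)
            impl = betweenness_centrality(net)
            oracle = brute_force_betweenness(net)
            for n in net.nodes:
                assert impl[n] == pytest.approx(oracle[n], abs=1e-12)

    def test_isolated_and_pendant_nodes_score_zero(self, net_builder):
        net = net_builder(["a", "b", "c", "iso"],
                          [("a", "b", 0.3), ("b", "c", 0.3)])
        bet = betweenness_centrality(net)
        assert bet["a"] == bet["c"] == bet["iso"] == 0.0


class TestSummaryTable:
    def test_sorted_by_eigenvector_descending(self, net_builder):
        rng = np.random.default_rng(5)
        net = random_network(rng, 10, 0.4, net_builder)
        table, _ = summary_table(net)
        eig = table["eigenvector"].to_numpy()
        assert (np.diff(eig) <= 1e-12).all()

    def test_isolated_node_row_is_all_zero(self, net_builder):
        net = net_builder(["a", "b", "iso"], [("a", "b", 0.4)])
        table, _ = summary_table(net)
        assert (table.loc["iso"] == 0).all()

    def test_handshake_lemma(self, net_builder):
        rng = np.random.default_rng(6)
        for _ in range(10):
            net = random_network(rng, 12, 0.3, net_builder)
            table, edges = summary_table(net)
            assert table["degree"].sum() == 2 * net.n_edges
            assert int(edges["retained"].sum()) == net.n_edges

    def test_edge_report_schema(self, net_builder):
        net = net_builder(["a", "b", "c"], [("a", "b", -0.4)])
        _, edges = summary_table(net)
        assert list(edges.columns) == [
            "node_a", "node_b", "partial_correlation", "z", "lfdr", "retained", "sign",
        ]
        row = edges[edges["retained"]].iloc[0]
        assert row["sign"] == -1 and row["partial_correlation"] == -0.4
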