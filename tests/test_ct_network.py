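"""Bipartite C-T network construction, metrics and Cytoscape interchange."""

import itertools
import random
from collections import deque

import networkx as nx
import pytest

from phytonet.ct_network import (
    betweenness_all,
    build_network,
    centralization,
    degree_all,
    export_network,
    heterogeneity,
    hub_rank,
    import_network,
    mean_targets_per_compound,
    summarize_network,
)


def bipartite(n_c, n_t, edges):
    pairs = [(f"c{i}", f"t{j}") for i, j in edges]
    return build_network(pairs, compounds=[f"c{i}" for i in range(n_c)],
                         targets=[f"t{j}" for j in range(n_t)])


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Independent oracle: enumerate every shortest path explicitly."""
    nodes = list(graph)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if t not in dist:
            continue
        # enumerate all shortest s-t paths by DFS along decreasing distance from t
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for v in graph.neighbors(head):
                if v in dist and dist[v] == dist[head] - 1:
                    stack.append(path + [v])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: s * norm for v, s in score.items()}


class TestBuildNetwork:
    def test_duplicate_pairs_collapse(self):
        net = build_network([("c1", "t1"), ("c1", "t1")])
        assert net.n_edges == 1

    def test_isolated_declared_nodes_kept(self):
        net = build_network([], compounds=["c1"], targets=["t1"])
        assert net.n_nodes == 2 and net.n_edges == 0

    def test_partition_clash_rejected(self):
        with pytest.raises(ValueError, match="both partitions"):
            build_network([("x", "t1")], compounds=["x"], targets=["x"])

    def test_bipartite_invariant(self):
        net = bipartite(4, 3, [(0, 0), (1, 1), (2, 2), (3, 0)])
        assert nx.is_bipartite(net.graph)


class TestDegree:
    def test_star(self):
        net = bipartite(1, 5, [(0, j) for j in range(5)])
        degrees = degree_all(net)
        assert degrees["c0"] == 5
        assert all(degrees[f"t{j}"] == 1 for j in range(5))

    def test_equals_incidence_row_sums(self):
        rng = random.Random(17)
        edges = {(rng.randrange(6), rng.randrange(8)) for _ in range(20)}
        net = bipartite(6, 8, edges)
        degrees = degree_all(net)
        for i in range(6):
            assert degrees[f"c{i}"] == sum(1 for a, b in edges if a == i)

    def test_handshake(self):
        rng = random.Random(4)
        edges = {(rng.randrange(5), rng.randrange(7)) for _ in range(15)}
        net = bipartite(5, 7, edges)
        degrees = degree_all(net)
        c_sum = sum(degrees[c] for c in net.compounds)
        t_sum = sum(degrees[t] for t in net.targets)
        assert c_sum == t_sum == net.n_edges


class TestBetweenness:
    def test_path_of_three(self):
        net = build_network([("c1", "t1"), ("c2", "t1")])
        b = betweenness_all(net)
        assert b["t1"] == pytest.approx(1.0)
        assert b["c1"] == b["c2"] == 0.0

    def test_k22_symmetric(self):
        net = bipartite(2, 2, [(i, j) for i in range(2) for j in range(2)])
        values = set(round(v, 12) for v in betweenness_all(net).values())
        assert len(values) == 1

    def test_small_networks_all_zero(self):
        net = build_network([("c1", "t1")])
        assert set(betweenness_all(net).values()) == {0.0}

    def test_matches_exhaustive_oracle(self):
        """Brandes result equals explicit shortest-path enumeration, n <= 8."""
        rng = random.Random(99)
        checked = 0
        while checked < 60:
            n_c, n_t = rng.randint(1, 4), rng.randint(1, 4)
            edges = {(rng.randrange(n_c), rng.randrange(n_t))
                     for _ in range(rng.randint(1, n_c * n_t))}
            net = bipartite(n_c, n_t, edges)
            if net.n_nodes < 3:
                continue
            expected = brute_force_betweenness(net.graph)
            actual = betweenness_all(net)
            for v in expected:
                assert actual[v] == pytest.approx(expected[v], abs=1e-12)
            checked += 1


class TestCentralization:
    def test_star_is_one(self):
        net = bipartite(1, 7, [(0, j) for j in range(7)])
        assert centralization(net) == pytest.approx(1.0)

    def test_regular_graph_is_zero(self):
        net = bipartite(3, 3, [(i, j) for i in range(3) for j in range(3)])
        assert centralization(net) == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        rng = random.Random(2)
        edges = {(rng.randrange(5), rng.randrange(6)) for _ in range(18)}
        net = bipartite(5, 6, edges)
        n, m = net.n_nodes, net.n_edges
        max_deg = max(degree_all(net).values())
        expected = (n / (n - 2)) * (max_deg / (n - 1) - 2 * m / (n * (n - 1)))
        assert centralization(net) == pytest.approx(expected)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            centralization(build_network([("c1", "t1")]))


class TestHeterogeneity:
    def test_regular_is_zero(self):
        net = bipartite(2, 2, [(i, j) for i in range(2) for j in range(2)])
        assert heterogeneity(net) == pytest.approx(0.0)

    def test_path_degrees_1_1_2(self):
        net = build_network([("c1", "t1"), ("c2", "t1")])
        assert heterogeneity(net) == pytest.approx(0.3536, abs=1e-4)

    def test_all_isolated_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity(build_network([], compounds=["c1"], targets=["t1"]))


class TestHubRank:
    def test_k_zero_empty(self):
        net = build_network([("c1", "t1")])
        assert hub_rank(net, 0) == []

    def test_deterministic_and_degree_sorted(self):
        rng = random.Random(8)
        edges = {(rng.randrange(6), rng.randrange(6)) for _ in range(20)}
        net = bipartite(6, 6, edges)
        first = hub_rank(net, 12)
        degrees = degree_all(net)
        assert first == hub_rank(net, 12)
        assert all(degrees[a] >= degrees[b] for a, b in zip(first, first[1:]))

    def test_fixture_targets_headed_by_mif_and_maob(self):
        from phytonet.synthetic_data import fixture_target_network

        net = fixture_target_network()
        top = hub_rank(net, 2, partition="target")
        assert set(top) == {"MIF", "MAOB"}


class TestMeanTargetsPerCompound:
    def test_k23(self):
        net = bipartite(2, 3, [(i, j) for i in range(2) for j in range(3)])
        assert mean_targets_per_compound(net) == (3.0, 3)

    def test_single_edge(self):
        assert mean_targets_per_compound(build_network([("c1", "t1")])) == (1.0, 1)

    def test_no_compounds_rejected(self):
        with pytest.raises(ValueError):
            mean_targets_per_compound(build_network([], targets=["t1"]))


class TestExport:
    def test_single_edge_sif(self):
        sif, attrs = export_network(build_network([("c1", "t1")]))
        assert sif == "c1\tct\tt1\n"
        assert "node_id\tpartition\tdegree\tbetweenness" in attrs

    def test_empty_network(self):
        sif, attrs = export_network(build_network([]))
        assert sif == ""
        assert attrs.startswith("node_id")

    def test_roundtrip(self):
        rng = random.Random(5)
        edges = {(rng.randrange(5), rng.randrange(5)) for _ in range(12)}
        net = bipartite(5, 5, edges)
        back = import_network(*export_network(net))
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, net.graph.edges))


def test_metrics_invariant_under_relabeling():
    rng = random.Random(31)
    edges = {(rng.randrange(4), rng.randrange(5)) for _ in range(12)}
    net = bipartite(4, 5, edges)
    renamed = build_network([(f"X{c}", f"Y{t}") for c, t in edges],
                            compounds=[f"X{i}" for i in range(4)],
                            targets=[f"Y{j}" for j in range(5)])
    assert sorted(degree_all(net).values()) == sorted(degree_all(renamed).values())
    assert centralization(net) == pytest.approx(centralization(renamed))
    assert heterogeneity(net) == pytest.approx(heterogeneity(renamed))
    s1, s2 = summarize_network(net), summarize_network(renamed)
    assert s1.n_edges == s2.n_edges
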