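import networkx as nx
import numpy as np
import pytest

from dynregnet.simulate import generate_static_network
from dynregnet.topology import (
    betweenness,
    centralization,
    closeness,
    clustering_coefficient,
    degrees,
    path_metrics,
    random_subnetwork_ensemble,
    summarize,
)

from .oracles import (
    brute_betweenness,
    brute_closeness,
    brute_path_metrics,
)


def digraph(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def undirected_as_digraph(edges):
    g = nx.DiGraph()
    for u, v in edges:
        g.add_edge(u, v)
        g.add_edge(v, u)
    return g


class TestDegrees:
    def test_directed_path(self):
        d = degrees(digraph([("a", "b"), ("b", "c")]))
        assert d.loc["b"].tolist()[:3] == [1, 1, 2]

    def test_isolated_node(self):
        d = degrees(digraph([], nodes=["x"]))
        assert d.loc["x"].sum() == 0

    def test_handshake(self):
        g = nx.gnp_random_graph(20, 0.2, seed=1, directed=True)
        assert degrees(g)["degree"].sum() == 2 * g.number_of_edges()


class TestClustering:
    def test_undirected_triangle(self):
        g = undirected_as_digraph([("a", "b"), ("b", "c"), ("a", "c")])
        # each node: 2 neighbors, both directions present among them
        assert clustering_coefficient(g, "a") == 1.0

    def test_directed_half(self):
        g = digraph([("n", "a"), ("n", "b"), ("a", "b")])
        assert clustering_coefficient(g, "n") == 0.5

    def test_star_center_zero(self):
        g = digraph([("c", "x"), ("c", "y"), ("c", "z")])
        assert clustering_coefficient(g, "c") == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(10, 0.3, seed=3, directed=True)
        perm = rng.permutation(10)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in g.nodes})
        for v in g.nodes:
            assert clustering_coefficient(g, v) == pytest.approx(
                clustering_coefficient(h, int(perm[v]))
            )


class TestCentrality:
    def test_path_center_betweenness(self):
        bc = betweenness(digraph([("a", "b"), ("b", "c")]))
        assert bc["b"] == pytest.approx(0.5)  # one (s,t) pair / (n-1)(n-2)
        assert bc["a"] == 0.0

    def test_small_graph_all_zero(self):
        assert betweenness(digraph([("a", "b")])) == {"a": 0.0, "b": 0.0}

    def test_star_center_closeness(self):
        g = undirected_as_digraph([("c", "x"), ("c", "y"), ("c", "z")])
        assert closeness(g)["c"] == pytest.approx(1.0)

    def test_path_end_closeness(self):
        g = undirected_as_digraph([("a", "b"), ("b", "c")])
        assert closeness(g)["a"] == pytest.approx(2.0 / 3.0)

    def test_single_node_closeness_zero(self):
        assert closeness(digraph([], nodes=["a"]))["a"] == 0.0


class TestPathMetrics:
    def test_directed_path(self):
        diameter, apl = path_metrics(digraph([("a", "b"), ("b", "c")]))
        assert diameter == 2.0
        assert apl == pytest.approx(4.0 / 3.0)

    def test_complete_triangle(self):
        g = undirected_as_digraph([("a", "b"), ("b", "c"), ("a", "c")])
        assert path_metrics(g) == (1.0, 1.0)

    def test_no_edges(self):
        assert path_metrics(digraph([], nodes=["a", "b"])) == (0.0, 0.0)


class TestCentralization:
    def test_star_is_one(self):
        g = undirected_as_digraph([("c", f"x{i}") for i in range(5)])
        assert centralization(g) == pytest.approx(1.0)

    def test_cycle_is_zero(self):
        g = undirected_as_digraph([("a", "b"), ("b", "c"), ("c", "a")])
        assert centralization(g) == 0.0

    def test_path_hand_value(self):
        g = undirected_as_digraph([("a", "b"), ("b", "c")])
        assert centralization(g) == pytest.approx(1.0)


class TestOracleAgreement:
    """Exact agreement with hand-rolled all-pairs BFS / path counting."""

    @pytest.mark.parametrize("batch", range(5))
    def test_random_digraphs(self, batch):
        rng = np.random.default_rng(100 + batch)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(
                n, 0.25, seed=int(rng.integers(2**31)), directed=True
            )
            bc, oracle_bc = betweenness(g), brute_betweenness(g)
            for v in g.nodes:
                assert bc[v] == pytest.approx(oracle_bc[v], abs=1e-12)
            cc, oracle_cc = closeness(g), brute_closeness(g)
            for v in g.nodes:
                assert cc[v] == pytest.approx(oracle_cc[v], abs=1e-12)
            assert path_metrics(g) == pytest.approx(brute_path_metrics(g))


class TestSummarize:
    def test_edgeless_graph_all_zero(self):
        report = summarize(digraph([], nodes=["a", "b", "c"]))
        for key in ("average_degree", "clustering_coefficient", "diameter",
                    "average_path_length", "betweenness", "closeness"):
            assert report.network[key] == 0.0

    def test_schema(self):
        report = summarize(digraph([("a", "b")]))
        assert set(report.per_node.columns) == {
            "in_degree", "out_degree", "degree", "clustering",
            "betweenness", "closeness", "role",
        }

    def test_means_are_hand_averages(self):
        g = nx.gnp_random_graph(8, 0.4, seed=2, directed=True)
        report = summarize(g)
        assert report.network["betweenness"] == pytest.approx(
            np.mean(list(betweenness(g).values()))
        )


class TestRandomEnsemble:
    def test_full_network_sampling_degenerate(self):
        net = generate_static_network(5, 30, 6, 5, seed=0)
        stats = random_subnetwork_ensemble(net, 5, 30, n_reps=10, seed=1)
        full = summarize(net.graph).network
        for key, value in stats.mean.items():
            assert value == pytest.approx(full[key])
            assert stats.sd[key] == pytest.approx(0.0, abs=1e-12)

    def test_proper_subsampling_varies(self):
        net = generate_static_network(12, 120, 8, 10, seed=3)
        stats = random_subnetwork_ensemble(net, 5, 40, n_reps=30, seed=2)
        assert stats.n_reps == 30
        assert stats.sd["average_degree"] > 0

    def test_determinism(self):
        net = generate_static_network(8, 50, 5, 4, seed=4)
        a = random_subnetwork_ensemble(net, 4, 20, n_reps=5, seed=9)
        b = random_subnetwork_ensemble(net, 4, 20, n_reps=5, seed=9)
        assert a.mean == b.mean

    def test_oversampling_rejected(self):
        net = generate_static_network(3, 10, 2, 0, seed=0)
        with pytest.raises(ValueError):
            random_subnetwork_ensemble(net, 4, 5, n_reps=2, seed=0)
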