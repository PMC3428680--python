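import networkx as nx
import numpy as np
import pytest

import rmtnet
from helpers import (
    brute_force_clustering,
    brute_force_paths,
    net_from_edges,
    net_from_graph,
    random_net,
)
from rmtnet.similarity import SimilarityMatrix
from rmtnet.topology import (
    build_network,
    fit_power_law,
    fit_scaling_law,
    global_topology,
    node_topology,
    noise_robustness,
)


class TestBuildNetwork:
    def test_triangle_from_pairwise_similarities(self):
        s = np.full((3, 3), 0.9)
        np.fill_diagonal(s, 1.0)
        sim = SimilarityMatrix(["a", "b", "c"], s, np.ones((3, 3), dtype=int))
        net = build_network(sim, 0.76)
        assert net.n == 3 and net.L == 3

    def test_negative_correlation_gives_signed_edge(self):
        s = np.array([[1, 0.9, 0.1], [0.9, 1, 0.9], [0.1, 0.9, 1]])
        signs = np.array([[1, -1, 1], [-1, 1, 1], [1, 1, 1]])
        sim = SimilarityMatrix(["a", "b", "c"], s, signs)
        net = build_network(sim, 0.76)
        assert net.graph["a"]["b"]["sign"] == -1

    def test_isolated_otu_dropped(self):
        s = np.array([[1, 0.9, 0.5], [0.9, 1, 0.5], [0.5, 0.5, 1]])
        sim = SimilarityMatrix(["a", "b", "lone"], s, np.ones((3, 3), dtype=int))
        net = build_network(sim, 0.76)
        assert "lone" not in net.node_ids

    def test_empty_network_is_an_error(self):
        s = np.eye(3)
        sim = SimilarityMatrix(["a", "b", "c"], s, np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="empty network"):
            build_network(sim, 0.76)


class TestNodeIndices:
    def test_path_graph_centralities(self, path3):
        df = node_topology(path3)
        assert df.loc["2", "B"] == 1.0
        assert df.loc["2", "SC"] == 1.0
        assert df.loc["1", "B"] == 0.0
        assert df.loc["3", "B"] == 0.0

    def test_triangle_clustering_and_vulnerability(self, triangle):
        df = node_topology(triangle)
        assert (df["CC"] == 1.0).all()
        assert np.allclose(df["V"], 0.0)

    def test_star_center_has_zero_clustering(self, star4):
        df = node_topology(star4)
        assert df.loc["c", "CC"] == 0.0

    def test_cycle_eigenvector_centrality_uniform(self):
        net = net_from_graph(nx.cycle_graph(6))
        df = node_topology(net)
        assert np.allclose(df["EC"], 1.0 / np.sqrt(6))

    def test_degree_sum_is_twice_link_count(self, community_net):
        df = node_topology(community_net)
        assert df["k"].sum() == 2 * community_net.L


class TestGlobalIndices:
    def test_triangle_closed_forms(self, triangle):
        g = global_topology(triangle)
        assert g.avg_k == pytest.approx(2.0)
        assert g.gd == pytest.approx(1.0)
        assert g.efficiency == pytest.approx(1.0)
        assert g.hd == pytest.approx(1.0)
        assert g.density == pytest.approx(1.0)
        assert g.avg_cc == pytest.approx(1.0)
        assert g.transitivity == pytest.approx(1.0)
        assert g.connectedness == pytest.approx(1.0)
        assert g.cd == 0.0 and g.cb == 0.0 and g.cs == 0.0
        assert g.ce == pytest.approx(0.0, abs=1e-9)

    def test_star_closed_forms(self, star4):
        g = global_topology(star4)
        assert g.cd == pytest.approx(1.0)
        assert g.gd == pytest.approx(1.5)
        assert g.efficiency == pytest.approx(0.75)
        assert g.hd == pytest.approx(4.0 / 3.0)
        assert g.density == pytest.approx(0.5)
        assert g.transitivity == 0.0
        assert g.cb == pytest.approx(1.0)  # the star attains its own maximum

    def test_two_disjoint_edges_unreachable_pairs(self):
        net = net_from_edges([("a", "b"), ("c", "d")])
        g = global_topology(net)
        assert g.unreachable_pairs == 4
        assert g.connectedness == pytest.approx(1.0 - 4.0 / 6.0)

    def test_deleting_an_edge_never_shrinks_geodesics(self):
        base = net_from_graph(nx.connected_watts_strogatz_graph(12, 4, 0.3, seed=3))
        g0 = global_topology(base)
        h = base.graph.copy()
        u, v = sorted(h.edges())[0]
        h.remove_edge(u, v)
        h.remove_nodes_from(list(nx.isolates(h)))
        g1 = global_topology(net_from_graph(h))
        assert g1.gd >= g0.gd - 1e-12


class TestBruteForceOracle:
    """Exact agreement with exhaustive shortest-path enumeration."""

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 26))
        p = float(rng.uniform(0.15, 0.5))
        net = random_net(n, p, seed)
        if net is None:
            pytest.skip("edgeless draw")
        df = node_topology(net)
        glob = global_topology(net)
        B, SC, gd, eff = brute_force_paths(net)
        cc = brute_force_clustering(net)
        for u in net.node_ids:
            assert df.loc[u, "SC"] == SC[u]
            assert df.loc[u, "B"] == pytest.approx(B[u], abs=1e-9)
            assert df.loc[u, "CC"] == pytest.approx(cc[u], abs=1e-12)
        assert glob.gd == pytest.approx(gd, abs=1e-12)
        assert glob.efficiency == pytest.approx(eff, abs=1e-12)


class TestDistributionFits:
    def test_power_law_on_constructed_degree_sequence(self):
        counts = {k: round(64 * k**-2) for k in range(1, 7)}
        seq = [k for k, c in counts.items() for _ in range(c)]
        net = net_from_graph(nx.havel_hakimi_graph(seq))
        fit = fit_power_law(net)
        assert fit.ok
        assert fit.r2 >= 0.99
        assert fit.exponent == pytest.approx(2.0, abs=0.2)

    def test_two_distinct_degrees_refused(self, star4):
        fit = fit_power_law(star4)  # degrees 1 and 3 only
        assert not fit.ok

    def test_regular_graph_refused(self):
        fit = fit_power_law(net_from_graph(nx.cycle_graph(8)))
        assert not fit.ok

    @staticmethod
    def hierarchy_fixture():
        """C(k) = 1/k exactly at k in {2, 3, 5, 9}: hubs of degree 3/5/9
        with (k-1)/2 leaf-pair edges give CC = 1/k; the CC=1 paired leaves
        (degree 2) are balanced by an equal number of CC=0 path middles."""
        g = nx.Graph()
        for name, k, pairs in (("H3", 3, 1), ("H5", 5, 2), ("H9", 9, 4)):
            leaves = [f"{name}L{i}" for i in range(k)]
            for u in leaves:
                g.add_edge(name, u)
            for i in range(pairs):
                g.add_edge(leaves[2 * i], leaves[2 * i + 1])
        for p in range(7):
            nx.add_path(g, [f"P{p}{c}" for c in "abcd"])
        return net_from_graph(g)

    def test_scaling_law_exact_inverse_relation(self):
        fit = fit_scaling_law(self.hierarchy_fixture())
        assert fit.ok
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_clustering_gives_zero_slope(self):
        g = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(5), nx.complete_graph(6)]
        )
        fit = fit_scaling_law(net_from_graph(g))
        assert fit.ok
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_triangle_free_graph_refused(self):
        fit = fit_scaling_law(net_from_graph(nx.cycle_graph(12)))
        assert not fit.ok


class TestNoiseRobustness:
    def test_zero_noise_preserves_everything(self, community, community_scan):
        df = noise_robustness(
            community.table, community_scan.final_threshold, [0.0], reps=2, seed=0
        )
        assert df.loc[0.0, "preserved"] == 1.0
        assert df.loc[0.0, "precision"] == 1.0

    def test_overlap_decays_with_noise(self, community, community_scan):
        df = noise_robustness(
            community.table,
            community_scan.final_threshold,
            [0.0, 0.3, 2.0],
            reps=3,
            seed=0,
        )
        assert df["preserved"].iloc[-1] < df["preserved"].iloc[0]

    def test_requires_relative_table(self, community):
        raw = rmtnet.AbundanceTable(
            community.table.otu_ids,
            community.table.sample_ids,
            community.table.values * 100,
            stage="raw",
        )
        with pytest.raises(ValueError, match="relative"):
            noise_robustness(raw, 0.5, [0.0], reps=1, seed=0)
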