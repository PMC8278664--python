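import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicblocks.network import (
    GeneCluster,
    SpiciParams,
    build_network,
    density,
    spici_cluster,
    support,
    tune_clustering,
)
from omicblocks.preprocess import ExpressionMatrix

from conftest import make_clique_graph


def expr_with_correlations():
    """Four genes with exact sample correlations: corr(a,b)=1, corr(a,c)=-0.9,
    corr(a,d)=0.15 (u and w are orthogonal, zero-mean, equal-norm)."""
    u = np.array([1.0, -1.0, 1.0, -1.0])
    w = np.array([1.0, 1.0, -1.0, -1.0])
    df = pd.DataFrame(
        {
            "a": u,
            "b": 2.0 * u + 3.0,  # corr exactly 1
            "c": -(0.9 * u + np.sqrt(1 - 0.81) * w),  # corr exactly -0.9
            "d": 0.15 * u + np.sqrt(1 - 0.15**2) * w,  # corr exactly 0.15
            "flat": np.ones(4),
        },
        index=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(df)


class TestBuildNetwork:
    def test_weights_are_absolute_correlations(self):
        e = expr_with_correlations()
        net = build_network(e, [("a", "b"), ("a", "c"), ("a", "d")])
        assert net.edges["a", "b"]["weight"] == pytest.approx(1.0)
        assert net.edges["a", "c"]["weight"] == pytest.approx(0.9)
        assert not net.has_edge("a", "d")  # |r| = 0.15 <= 0.2

    def test_constant_profile_skipped(self):
        e = expr_with_correlations()
        net = build_network(e, [("a", "flat"), ("a", "b")])
        assert not net.has_edge("a", "flat")
        assert net.has_edge("a", "b")

    def test_non_ppi_pairs_absent_and_unknown_genes_ignored(self):
        e = expr_with_correlations()
        net = build_network(e, [("a", "b"), ("a", "zzz")])
        assert not net.has_edge("a", "c")
        assert "zzz" not in net

    def test_sample_permutation_invariance(self):
        e = expr_with_correlations()
        perm = ExpressionMatrix(e.data.iloc[[2, 0, 3, 1]])
        ppi = [("a", "b"), ("a", "c"), ("b", "c")]
        n1, n2 = build_network(e, ppi), build_network(perm, ppi)
        for u, v, d in n1.edges(data=True):
            assert n2.edges[u, v]["weight"] == pytest.approx(d["weight"])


class TestSupportAndDensity:
    def test_support_sums_edge_weights_into_set(self, triangle_graph):
        net = nx.Graph()
        net.add_edge("u", "x", weight=0.3)
        net.add_edge("u", "y", weight=0.5)
        net.add_edge("u", "z", weight=0.4)
        assert support("u", {"x", "y"}, net) == pytest.approx(0.8)
        assert support("u", set(), net) == 0.0
        assert support("u", {"z"}, net) == pytest.approx(0.4)
        assert support("u", {"not_a_neighbor"}, net) == 0.0

    def test_density_hand_values(self, triangle_graph):
        assert density({"A", "B", "C"}, triangle_graph) == pytest.approx(1.0)
        pair = nx.Graph()
        pair.add_edge("A", "B", weight=0.6)
        assert density({"A", "B"}, pair) == pytest.approx(0.6)
        path = nx.Graph()
        for a, b in [("A", "B"), ("B", "C"), ("C", "D")]:
            path.add_edge(a, b, weight=0.5)
        assert density({"A", "B", "C", "D"}, path) == pytest.approx(0.25)

    def test_density_needs_two_vertices(self, triangle_graph):
        with pytest.raises(ValueError):
            density({"A"}, triangle_graph)


class TestSpici:
    def test_two_disjoint_triangles_recovered(self):
        net = make_clique_graph([["a1", "a2", "a3"], ["b1", "b2", "b3"]])
        clusters = spici_cluster(net, SpiciParams(min_cluster_size=3))
        assert len(clusters) == 2
        assert sorted(tuple(sorted(c.genes)) for c in clusters) == [
            ("a1", "a2", "a3"),
            ("b1", "b2", "b3"),
        ]

    def test_too_small_network_yields_nothing(self):
        net = nx.Graph()
        net.add_edge("x", "y", weight=0.9)
        assert spici_cluster(net, SpiciParams(min_cluster_size=5)) == []

    @pytest.mark.parametrize("k,size", [(2, 4), (3, 5), (4, 3), (5, 6)])
    def test_planted_cliques_recovered_exactly(self, k, size):
        cliques = [[f"c{i}_{j:02d}" for j in range(size)] for i in range(k)]
        net = make_clique_graph(cliques, weight=0.9)
        clusters = spici_cluster(net, SpiciParams(min_cluster_size=min(size, 3)))
        assert sorted(tuple(sorted(c.genes)) for c in clusters) == sorted(
            tuple(sorted(c)) for c in cliques
        )

    def test_clusters_disjoint_and_bounds_recomputed(self):
        rng = np.random.default_rng(11)
        net = nx.gnm_random_graph(60, 240, seed=3)
        net = nx.relabel_nodes(net, {i: f"g{i:02d}" for i in net.nodes})
        for _, _, d in net.edges(data=True):
            d["weight"] = float(rng.uniform(0.25, 1.0))
        params = SpiciParams(0.3, 0.5, 3)
        clusters = spici_cluster(net, params)
        seen = set()
        for c in clusters:
            assert not (c.genes & seen)
            seen |= c.genes
            assert len(c.genes) >= params.min_cluster_size
            # independent recomputation of the emitted density
            assert density(c.genes, net) == pytest.approx(c.density)
            assert c.density >= params.min_cluster_density

    def test_default_params_match_lung_cohort_settings(self):
        params = SpiciParams()
        assert (params.min_cluster_density, params.min_support_threshold,
                params.min_cluster_size) == (0.1, 0.4, 5)

    def test_param_intervals_enforced(self):
        with pytest.raises(ValueError):
            SpiciParams(min_cluster_density=0.05)
        with pytest.raises(ValueError):
            SpiciParams(min_support_threshold=0.8)
        with pytest.raises(ValueError):
            SpiciParams(min_cluster_size=1)


class TestTuneClustering:
    def test_planted_modules_yield_target_cluster_count(self):
        cliques = [[f"m{i:03d}_{j}" for j in range(10)] for i in range(120)]
        net = make_clique_graph(cliques, weight=0.9)
        params, clusters = tune_clustering(net)
        assert 100 <= len(clusters) <= 200
        assert all(5 <= len(c) <= 100 for c in clusters)

    def test_infeasible_grid_warns_and_returns_closest(self):
        net = make_clique_graph([["a", "b", "c"], ["d", "e", "f"]])
        with pytest.warns(UserWarning, match="closest"):
            params, clusters = tune_clustering(net, sizes=(3,))
        assert isinstance(params, SpiciParams)

    def test_empty_grid_rejected(self):
        net = make_clique_graph([["a", "b", "c"]])
        with pytest.raises(ValueError):
            tune_clustering(net, densities=())
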