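"""Correlation network: p-values, thresholding, centralities, modules."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicnet.connectome import (
    ConnectomeGraph,
    build_graph,
    centralities,
    correlation_p,
    detect_clusters,
    edge_table,
    export_graphml,
    hub_ranking,
    interomic_connectivity,
    standardize_and_correlate,
)
from omicnet.errors import ConfigError, InsufficientDataError
from omicnet.io import OmicsLayer

from oracles import centrality_oracle


def _graph_from_nx(g: nx.Graph) -> ConnectomeGraph:
    h = nx.Graph()
    for n in g.nodes:
        h.add_node(str(n), layer="rna", symbol=str(n))
    for u, v in g.edges:
        h.add_edge(str(u), str(v), r=0.9, p=0.0, sign=1, inter=False)
    return ConnectomeGraph(graph=h, n_samples=90, r_threshold=0.7)


def _assert_matches_oracle(g: nx.Graph, tol=1e-8):
    cg = _graph_from_nx(g)
    table = centralities(cg)
    nodes = sorted(cg.graph.nodes)
    adj = nx.to_numpy_array(cg.graph, nodelist=nodes, weight=None)
    oracle = centrality_oracle(adj)
    for metric in ("degree", "betweenness", "closeness", "eigenvector"):
        got = table.loc[nodes, metric].to_numpy(dtype=float)
        np.testing.assert_allclose(got, oracle[metric], atol=tol, err_msg=metric)


class TestCorrelationP:
    def test_published_threshold_pvalues(self):
        """r=0.7 and r=0.75 at n=90 give the published network p cutoffs."""
        assert correlation_p(0.7, 90) == pytest.approx(1.63e-14, rel=5e-3)
        assert correlation_p(0.75, 90) == pytest.approx(1.79e-17, rel=5e-3)

    def test_zero_correlation_gives_p1(self):
        assert correlation_p(0.0, 10) == 1.0
        assert correlation_p(0.0, 1000) == 1.0

    def test_collinearity_returns_zero(self):
        assert correlation_p(1.0, 10) == 0.0
        assert correlation_p(-1.0, 10) == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.floats(0.01, 0.98),
        st.floats(0.01, 0.98),
        st.integers(5, 500),
        st.integers(5, 500),
    )
    def test_strictly_decreasing_in_abs_r_and_n(self, r1, r2, n1, n2):
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-6:
            assert correlation_p(hi, 50) < correlation_p(lo, 50)
        if n1 != n2:
            small, big = sorted((n1, n2))
            assert correlation_p(0.4, big) < correlation_p(0.4, small)
        assert correlation_p(-r1, 50) == pytest.approx(correlation_p(r1, 50))


class TestCorrelate:
    def _layers(self, arr, n_samples=10):
        cols = [f"S{i}" for i in range(n_samples)]
        df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols)
        return [OmicsLayer(layer_name="rna", values=df)]

    def test_diagonal_is_one_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        arr = np.vstack([x, -x, rng.normal(size=10)])
        R = standardize_and_correlate(self._layers(arr))
        assert R.iloc[0, 0] == pytest.approx(1.0)
        assert R.iloc[0, 1] == pytest.approx(-1.0)
        assert ((R.to_numpy() >= -1) & (R.to_numpy() <= 1)).all()
        assert np.allclose(R.to_numpy(), R.to_numpy().T)

    def test_independent_features_rarely_exceed_null_band(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 90))
        R = standardize_and_correlate(self._layers(arr, 90))
        assert abs(R.iloc[0, 1]) < 0.3

    def test_zero_variance_feature_dropped_with_warning(self, caplog):
        arr = np.vstack([np.ones(10), np.arange(10.0)])
        with caplog.at_level("WARNING"):
            R = standardize_and_correlate(self._layers(arr))
        assert list(R.index) == ["rna:g1"]

    def test_too_few_samples_raise(self):
        arr = np.random.default_rng(0).normal(size=(3, 2))
        with pytest.raises(InsufficientDataError):
            standardize_and_correlate(self._layers(arr, 2))


class TestBuildGraph:
    def _matrix(self, r_offdiag):
        ids = ["methylation:a", "rna:b", "protein:c"]
        R = np.full((3, 3), r_offdiag, dtype=float)
        np.fill_diagonal(R, 1.0)
        return pd.DataFrame(R, index=ids, columns=ids)

    def test_triangle_at_high_correlation(self):
        cg = build_graph(self._matrix(0.9), 0.7, n_samples=90)
        assert cg.graph.number_of_edges() == 3

    def test_all_below_threshold_gives_empty_graph(self):
        cg = build_graph(self._matrix(0.5), 0.7, n_samples=90)
        assert cg.graph.number_of_edges() == 0
        assert cg.graph.number_of_nodes() == 3

    def test_negative_correlation_kept_with_sign(self):
        cg = build_graph(self._matrix(-0.8), 0.7, n_samples=90)
        assert cg.graph.number_of_edges() == 3
        assert all(d["sign"] == -1 for _, _, d in cg.graph.edges(data=True))
        signed = build_graph(self._matrix(-0.8), 0.7, n_samples=90, signed_only=True)
        assert signed.graph.number_of_edges() == 0

    def test_edges_monotone_in_threshold(self, small_dataset):
        R = standardize_and_correlate(list(small_dataset.layers.values()))
        counts = [
            build_graph(R, thr, n_samples=90).graph.number_of_edges()
            for thr in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigError):
            build_graph(self._matrix(0.9), 1.5, n_samples=90)


class TestCentralities:
    def test_star_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1-4
        cg = _graph_from_nx(g)
        table = centralities(cg)
        assert table.loc["0", "degree"] == 4
        assert table.loc["0", "betweenness"] == pytest.approx(1.0)  # 6/6 pair paths
        assert all(table.loc[str(i), "betweenness"] == 0 for i in range(1, 5))
        assert table.loc["0", "closeness"] == pytest.approx(1.0)
        assert table.loc["0", "eigenvector"] == pytest.approx(1.0)

    def test_complete_graph_symmetry(self):
        table = centralities(_graph_from_nx(nx.complete_graph(4)))
        assert np.allclose(table["eigenvector"], 1.0)
        assert np.allclose(table["betweenness"], 0.0)

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        table = centralities(_graph_from_nx(g))
        assert table.loc["2"].drop("layer").tolist() == [0, 0.0, 0.0, 0.0]

    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.6), seed=seed)
        _assert_matches_oracle(g)

    def test_disconnected_graph_matches_oracle(self):
        g = nx.disjoint_union(nx.cycle_graph(4), nx.path_graph(3))
        g.add_node(99)
        _assert_matches_oracle(g)


class TestClusters:
    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        cg = _graph_from_nx(g)
        for method in ("components", "greedy_modularity"):
            cluster_of, n = detect_clusters(cg, method)
            assert n == 2
            assert len({cluster_of[str(i)] for i in range(3)}) == 1

    def test_edgeless_graph_has_zero_clusters(self):
        g = nx.empty_graph(5)
        _, n = detect_clusters(_graph_from_nx(g), "components")
        assert n == 0

    def test_cluster_count_matches_component_count_definitionally(self, small_dataset):
        R = standardize_and_correlate(list(small_dataset.layers.values()))
        cg = build_graph(R, 0.7, n_samples=90)
        _, n = detect_clusters(cg, "components")
        comps = [c for c in nx.connected_components(cg.graph) if len(c) > 1]
        assert n == len(comps)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            detect_clusters(_graph_from_nx(nx.path_graph(3)), "louvain")

    def test_planted_modules_recovered_end_to_end(self):
        from omicnet.experiments import module_recovery_replicate

        assert module_recovery_replicate(seed=12345) >= 0.9


class TestHubs:
    def test_star_center_is_unique_hub(self):
        hubs = hub_ranking(_graph_from_nx(nx.star_graph(4)), k=1)
        assert list(hubs.index) == ["0"]

    def test_twin_stars_tie_broken_by_id(self):
        g = nx.disjoint_union(nx.star_graph(3), nx.star_graph(3))  # centers 0, 4
        hubs = hub_ranking(_graph_from_nx(g), k=2)
        assert list(hubs.index) == ["0", "4"]

    def test_bridge_between_modules_tops_betweenness(self):
        # two cliques sharing one node: the shared node carries all
        # inter-clique shortest paths
        g = nx.complete_graph(5)
        h = nx.complete_graph(5)
        g = nx.disjoint_union(g, h)
        bridge = 10
        g.add_edges_from([(bridge, 0), (bridge, 5)])
        table = centralities(_graph_from_nx(g))
        assert table["betweenness"].idxmax() == str(bridge)

    def test_k_exceeding_nodes_returns_all_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            hubs = hub_ranking(_graph_from_nx(nx.path_graph(3)), k=10)
        assert len(hubs) == 3


class TestInterOmic:
    def _two_layer_graph(self, inter_edges, intra_edges):
        g = nx.Graph()
        for i in range(4):
            g.add_node(f"methylation:m{i}", layer="methylation", symbol=f"m{i}")
            g.add_node(f"rna:r{i}", layer="rna", symbol=f"r{i}")
        for u, v in inter_edges:
            g.add_edge(f"methylation:m{u}", f"rna:r{v}", r=0.9, p=0.0, sign=1, inter=True)
        for u, v in intra_edges:
            g.add_edge(f"rna:r{u}", f"rna:r{v}", r=0.9, p=0.0, sign=1, inter=False)
        return ConnectomeGraph(graph=g, n_samples=90, r_threshold=0.7)

    def test_all_within_one_layer_gives_zero(self):
        frac, counts = interomic_connectivity(self._two_layer_graph([], [(0, 1), (1, 2)]))
        assert frac == 0.0
        assert counts == {"rna|rna": 2}

    def test_bipartite_graph_gives_one(self):
        frac, counts = interomic_connectivity(
            self._two_layer_graph([(0, 0), (1, 1), (2, 3)], [])
        )
        assert frac == 1.0
        assert counts == {"methylation|rna": 3}

    def test_edgeless_graph_raises(self):
        with pytest.raises(InsufficientDataError):
            interomic_connectivity(self._two_layer_graph([], []))

    def test_cross_layer_modules_beat_within_layer_modules(self):
        from omicnet.experiments import interomic_contrast_replicate

        cross, within = interomic_contrast_replicate(seed=99)
        assert cross > within


def test_graphml_and_edge_table_roundtrip(tmp_path, small_dataset):
    R = standardize_and_correlate(list(small_dataset.layers.values()))
    cg = build_graph(R, 0.6, n_samples=90)
    centralities(cg)
    detect_clusters(cg)
    et = edge_table(cg)
    assert set(et.columns) == {"source", "target", "r", "p", "sign", "inter"}
    path = tmp_path / "g.graphml"
    export_graphml(cg, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == cg.graph.number_of_nodes()
    assert back.number_of_edges() == cg.graph.number_of_edges()
    some = next(iter(back.nodes))
    assert {"layer", "symbol", "cluster", "degree"} <= set(back.nodes[some])
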