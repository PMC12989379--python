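"""Multi-layer Pearson correlation network ("connectome") construction.

Selected features from all three omic layers are placed on one axis
(layer-namespaced ids), pairwise Pearson correlations are computed
across the cohort's samples, and pairs with |r| at or above a threshold
become edges of an undirected graph. Thresholding is on |r| — negative
correlations are kept as edges with a sign attribute, since
methylation-expression feature pairs are biologically anticorrelated
and discarding them would delete exactly the cross-layer links the
analysis is after; a signed-only mode restricts edges to positive r.

Node importance is scored by four standard centralities (degree,
pair-normalized shortest-path betweenness, within-component closeness,
per-component max-normalized eigenvector); modules are detected either
as connected components (default) or by greedy modularity maximization;
hubs are ranked by the mean of the four min-max-scaled centralities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from omicnet.errors import ConfigError, InsufficientDataError
from omicnet.io import OmicsLayer, display_symbol, layer_of

log = logging.getLogger(__name__)


@dataclass
class ConnectomeGraph:
    """Thresholded correlation graph plus derived annotations.

    ``graph`` is an undirected networkx graph whose nodes carry
    ``layer`` and ``symbol`` attributes and whose edges carry ``r``,
    ``p``, ``sign`` and ``inter`` (inter-omic flag). ``n_samples`` is
    the sample count the correlations were computed over.
    """

    graph: nx.Graph
    n_samples: int
    r_threshold: float
    cluster_of: dict[str, int] = field(default_factory=dict)
    centrality: pd.DataFrame | None = None


def standardize_and_correlate(
    layers: list[OmicsLayer], min_samples: int = 3
) -> pd.DataFrame:
    """Pearson correlation matrix over all selected features.

    Features from every layer share one namespaced axis; zero-variance
    features are removed with a logged warning. Requires >= 3 aligned
    samples.
    """
    sample_ids = layers[0].sample_ids
    for ly in layers[1:]:
        if ly.sample_ids != sample_ids:
            raise InsufficientDataError("layers are not sample-aligned")
    if len(sample_ids) < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} samples for correlations, got {len(sample_ids)}"
        )
    stacked = pd.concat([ly.namespaced() for ly in layers], axis=0)
    values = stacked.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(stacked.index[~keep])
        log.warning(
            "standardize_and_correlate: dropped %d zero-variance features: %s",
            len(dropped),
            dropped[:5],
        )
        stacked = stacked.loc[keep]
        values = values[keep]
    r = np.atleast_2d(np.corrcoef(values))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=stacked.index, columns=stacked.index)


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null.

    Uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2
    degrees of freedom. |r| = 1 (exact collinearity) returns 0.
    """
    if n < 3:
        raise InsufficientDataError("correlation_p: need n >= 3")
    r = float(r)
    if abs(r) > 1:
        raise ConfigError("correlation_p: |r| must be <= 1")
    if abs(r) == 1.0:
        log.warning("correlation_p: exact collinearity (|r|=1), p=0")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def build_graph(
    R: pd.DataFrame,
    r_threshold: float,
    n_samples: int,
    signed_only: bool = False,
) -> ConnectomeGraph:
    """Threshold the correlation matrix into an undirected graph.

    Every off-diagonal pair with |r| >= r_threshold (r >= threshold in
    signed-only mode) becomes one edge carrying r, its p-value and a
    sign attribute; all features stay in the graph so isolated nodes
    remain visible.
    """
    if not (0.0 < r_threshold < 1.0):
        raise ConfigError("r_threshold: must lie in (0,1)")
    ids = list(R.index)
    g = nx.Graph()
    for nid in ids:
        g.add_node(nid, layer=layer_of(nid), symbol=display_symbol(nid))
    rmat = R.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = rmat[iu, ju]
    hit = vals >= r_threshold if signed_only else np.abs(vals) >= r_threshold
    inter_count = 0
    for i, j, r in zip(iu[hit], ju[hit], vals[hit]):
        u, v = ids[i], ids[j]
        inter = layer_of(u) != layer_of(v)
        inter_count += inter
        g.add_edge(
            u,
            v,
            r=float(r),
            p=correlation_p(r, n_samples),
            sign=1 if r >= 0 else -1,
            inter=bool(inter),
        )
    log.info(
        "build_graph: %d nodes, %d edges (%d inter-omic) at |r|>=%g",
        g.number_of_nodes(),
        g.number_of_edges(),
        inter_count,
        r_threshold,
    )
    return ConnectomeGraph(graph=g, n_samples=n_samples, r_threshold=r_threshold)


# ---------------------------------------------------------------------------
# centralities

def _eigenvector_component(adj: np.ndarray) -> np.ndarray:
    """Perron vector of one connected component's adjacency matrix.

    Power iteration on A + I (the shift keeps bipartite components from
    oscillating), all-ones start, at most 1000 iterations, tolerance
    1e-10; the result is max-normalized to 1.
    """
    k = adj.shape[0]
    if k == 1:
        return np.zeros(1)
    m = adj + np.eye(k)
    x = np.ones(k)
    for _ in range(1000):
        x_new = m @ x
        x_new /= np.linalg.norm(x_new)
        if np.abs(x_new - x).max() < 1e-10:
            x = x_new
            break
        x = x_new
    x = np.abs(x)
    return x / x.max()


def centralities(cg: ConnectomeGraph) -> pd.DataFrame:
    """Four per-node centrality scores.

    degree: raw edge count. betweenness: unweighted shortest-path
    betweenness normalized by (n-1)(n-2)/2 node pairs. closeness:
    (k-1)/sum(d) within each connected component of size k. eigenvector:
    per-component power-iteration Perron score, max-normalized to 1.
    Isolated nodes score 0 everywhere by convention.
    """
    g = cg.graph
    if g.number_of_nodes() == 0:
        raise InsufficientDataError("centralities: empty graph")
    nodes = sorted(g.nodes)
    degree = {n: g.degree(n) for n in nodes}
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    eig = {n: 0.0 for n in nodes}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        adj = nx.to_numpy_array(g, nodelist=comp, weight=None)
        scores = _eigenvector_component(adj)
        for node, s in zip(comp, scores):
            eig[node] = float(s)
    table = pd.DataFrame(
        {
            "node": nodes,
            "layer": [g.nodes[n]["layer"] if "layer" in g.nodes[n] else "" for n in nodes],
            "degree": [degree[n] for n in nodes],
            "betweenness": [float(betweenness[n]) for n in nodes],
            "closeness": [float(closeness[n]) for n in nodes],
            "eigenvector": [eig[n] for n in nodes],
        }
    ).set_index("node")
    cg.centrality = table
    return table


def detect_clusters(cg: ConnectomeGraph, method: str = "components") -> tuple[dict[str, int], int]:
    """Partition non-isolated nodes into modules.

    ``components`` (default): connected components of the thresholded
    graph. ``greedy_modularity``: agglomerative modularity maximization.
    Cluster indices are 1-based, assigned in order of decreasing cluster
    size (ties broken by lexicographically smallest member); isolated
    nodes get index 0 and are excluded from the cluster count.
    """
    g = cg.graph
    if g.number_of_nodes() == 0:
        raise InsufficientDataError("detect_clusters: empty graph")
    if method == "components":
        groups = [c for c in nx.connected_components(g) if len(c) > 1]
    elif method == "greedy_modularity":
        sub = g.subgraph([n for n, d in g.degree() if d > 0])
        groups = (
            [set(c) for c in nx.community.greedy_modularity_communities(sub)]
            if sub.number_of_nodes()
            else []
        )
    else:
        raise ConfigError(f"cluster method: unknown method {method!r}")
    groups.sort(key=lambda c: (-len(c), min(c)))
    cluster_of = {n: 0 for n in g.nodes}
    for idx, members in enumerate(groups, start=1):
        for n in members:
            cluster_of[n] = idx
    cg.cluster_of = cluster_of
    log.info("detect_clusters(%s): %d clusters", method, len(groups))
    return cluster_of, len(groups)


def hub_ranking(cg: ConnectomeGraph, k: int = 10) -> pd.DataFrame:
    """Top-k hubs by the mean of the four min-max-scaled centralities.

    Each centrality is scaled to [0,1] over the whole graph (a constant
    column scales to 0); ties are broken lexicographically by node id.
    k larger than the node count returns all nodes with a warning.
    """
    if k < 1:
        raise ConfigError("k: must be >= 1")
    table = cg.centrality if cg.centrality is not None else centralities(cg)
    if k > len(table):
        log.warning("hub_ranking: k=%d exceeds node count %d", k, len(table))
        k = len(table)
    scaled = pd.DataFrame(index=table.index)
    for col in ("degree", "betweenness", "closeness", "eigenvector"):
        v = table[col].to_numpy(dtype=float)
        span = v.max() - v.min()
        scaled[col] = (v - v.min()) / span if span > 0 else 0.0
    out = table.copy()
    out["hub_score"] = scaled.mean(axis=1)
    out = out.sort_values(
        ["hub_score", "node"], ascending=[False, True], kind="mergesort"
    )
    return out.head(k)


def interomic_connectivity(cg: ConnectomeGraph) -> tuple[float, dict[str, int]]:
    """Fraction of edges linking different omic layers, plus pair counts.

    Returns (inter_edge_fraction, counts) where counts holds one entry
    per unordered layer pair (e.g. ``methylation|rna``) and per
    within-layer class (e.g. ``rna|rna``). Raises on an edgeless graph.
    """
    g = cg.graph
    if g.number_of_edges() == 0:
        raise InsufficientDataError("interomic_connectivity: graph has no edges")
    counts: dict[str, int] = {}
    inter = 0
    for u, v in g.edges:
        lu, lv = layer_of(u), layer_of(v)
        key = "|".join(sorted((lu, lv)))
        counts[key] = counts.get(key, 0) + 1
        inter += lu != lv
    return inter / g.number_of_edges(), counts


# ---------------------------------------------------------------------------
# export

def edge_table(cg: ConnectomeGraph) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "r": d["r"],
            "p": d["p"],
            "sign": d["sign"],
            "inter": d["inter"],
        }
        for u, v, d in cg.graph.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "r", "p", "sign", "inter"]
    ).sort_values(["source", "target"]).reset_index(drop=True)


def export_graphml(cg: ConnectomeGraph, path) -> None:
    """GraphML with cluster + centrality node attributes for viewers."""
    g = cg.graph.copy()
    table = cg.centrality if cg.centrality is not None else centralities(cg)
    for n in g.nodes:
        g.nodes[n]["cluster"] = int(cg.cluster_of.get(n, 0))
        for col in ("degree", "betweenness", "closeness", "eigenvector"):
            g.nodes[n][col] = float(table.loc[n, col])
    nx.write_graphml(g, path)
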