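"""Searchlight assembly on a vertex graph and max-cluster-size correction.

Statistics computed per searchlight are assigned back to vertices, and
vertex-wise p-maps are corrected for multiple comparisons by cluster
extent: clusters are connected components of vertices significant at the
uncorrected threshold, and only clusters larger than the 95th percentile
of the permutation null's *maximum* cluster size survive.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["build_searchlights", "vertex_stat_map", "cluster_threshold"]


def _node_order(graph: nx.Graph) -> list:
    return sorted(graph.nodes)


def build_searchlights(graph: nx.Graph, radius_vertices: int) -> dict:
    """Per center vertex, the set of vertices within ``radius_vertices`` hops.

    Radius 0 gives singleton searchlights; every vertex belongs to at
    least one searchlight (its own).  Raises on a disconnected graph,
    listing the components.
    """
    if radius_vertices < 0:
        raise ValueError("radius must be nonnegative")
    if not nx.is_connected(graph):
        comps = [sorted(c)[:5] for c in nx.connected_components(graph)]
        raise ValueError(f"graph is disconnected; components start with: {comps}")
    out = {}
    for v in _node_order(graph):
        reach = nx.single_source_shortest_path_length(graph, v, cutoff=radius_vertices)
        out[v] = sorted(reach)
    return out


def vertex_stat_map(
    searchlight_scores: dict,
    searchlights: dict,
    assignment: str = "center",
) -> dict:
    """Assign per-searchlight z scores back to vertices.

    center: each searchlight's score goes to its center vertex only.
    mean: each vertex averages the scores of every searchlight containing
    it (vertices in this design are covered by ~14 searchlights).
    """
    if assignment not in ("center", "mean"):
        raise ValueError("assignment must be 'center' or 'mean'")
    missing = set(searchlights) - set(searchlight_scores)
    if missing:
        raise ValueError(f"missing scores for searchlights: {sorted(missing)[:5]}")

    def _score(s):
        return float(s.z) if hasattr(s, "z") else float(s)

    if assignment == "center":
        return {v: _score(searchlight_scores[v]) for v in searchlights}
    sums: dict = {}
    counts: dict = {}
    for center, members in searchlights.items():
        z = _score(searchlight_scores[center])
        for m in members:
            sums[m] = sums.get(m, 0.0) + z
            counts[m] = counts.get(m, 0) + 1
    return {v: sums[v] / counts[v] for v in sums}


def _adjacency(graph: nx.Graph, order: list) -> csr_matrix:
    return nx.to_scipy_sparse_array(graph, nodelist=order, format="csr")


def _cluster_sizes(mask: np.ndarray, adj: csr_matrix) -> list[np.ndarray]:
    """Connected components (as vertex-index arrays) of the masked subgraph."""
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n, labels = connected_components(sub, directed=False)
    return [idx[labels == i] for i in range(n)]


def cluster_threshold(
    z_map: np.ndarray,
    graph: nx.Graph,
    p_map: np.ndarray,
    null_p_maps: np.ndarray,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.05,
) -> dict:
    """Max-cluster-size permutation correction of a vertex-wise map.

    p_map and each row of null_p_maps are per-vertex p-values from the
    same shuffling scheme (vertices ordered by sorted node id).  Clusters
    of p < cluster_forming_p are retained when their size exceeds the
    (1 - alpha) quantile of the null distribution of maximum cluster
    sizes.  Returns observed clusters, retained clusters, the null max
    sizes, and the size threshold.
    """
    null_p_maps = np.atleast_2d(np.asarray(null_p_maps, dtype=float))
    if null_p_maps.shape[0] == 0:
        raise ValueError("need at least one permutation map")
    order = _node_order(graph)
    if len(order) != len(p_map):
        raise ValueError("p_map length does not match vertex count")
    adj = _adjacency(graph, order)
    null_max = np.array(
        [
            max((len(c) for c in _cluster_sizes(row < cluster_forming_p, adj)), default=0)
            for row in null_p_maps
        ]
    )
    threshold = float(np.quantile(null_max, 1 - alpha))
    observed = _cluster_sizes(np.asarray(p_map) < cluster_forming_p, adj)
    clusters = []
    for comp in sorted(observed, key=len, reverse=True):
        size = len(comp)
        clusters.append(
            {
                "vertices": [order[i] for i in comp],
                "size": size,
                "null_percentile": float(np.mean(null_max < size)),
                "significant": size > threshold,
            }
        )
    return {
        "clusters": clusters,
        "significant": [c for c in clusters if c["significant"]],
        "null_max_sizes": null_max,
        "size_threshold": threshold,
        "z_map": np.asarray(z_map),
    }
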