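"""Weighted directed causal-network summary metrics.

A band-averaged DTF matrix defines a directed graph: nodes are electrodes
and ``weights[i, j]`` is the connection strength from source *j* to sink
*i*.  Raw DTF entries are generically all positive, so "nonzero" edges are
defined by a threshold; the three summaries are

* clustering coefficient C — mean over nodes of the fraction of ordered
  neighbour pairs (neighbourhood = union of in- and out-neighbours on the
  binary graph) that are themselves joined by a directed edge;
* network density D — realised binary edges over the N(N-1) possible;
* global efficiency E_global — mean inverse directed shortest-path length,
  with edge lengths the reciprocal of max-normalized weights (the strongest
  edge has length 1) and unreachable pairs contributing zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "CausalNetwork",
    "NetworkMetrics",
    "build_network",
    "clustering_coefficient",
    "network_density",
    "global_efficiency",
    "network_metrics",
]


@dataclass
class CausalNetwork:
    """Thresholded weighted digraph built from one band-averaged DTF matrix."""

    weights: np.ndarray  # (M, M), weights[i, j]: source j -> sink i
    threshold_theta: float
    binary_adj: np.ndarray  # boolean, weights > threshold

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.binary_adj.sum())

    def has_edge(self, source: int, target: int) -> bool:
        return bool(self.binary_adj[target, source])


@dataclass
class NetworkMetrics:
    C: float
    D: float
    E_global: float
    band_label: str = ""
    threshold_theta: float = 0.0


def build_network(band_matrix: np.ndarray, threshold_theta) -> CausalNetwork:
    """Threshold a DTF band matrix into a causal network.

    ``threshold_theta`` is either a float in [0, 1) or the string
    ``"median"`` (the matrix's own median off-diagonal value — note that on
    a single network this fixes the binary density at ~0.5, so comparisons
    across networks should share one externally supplied threshold).
    """
    w = np.asarray(band_matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"band matrix must be square, got {w.shape}")
    if np.any(w < 0):
        raise ValueError("DTF band matrix has negative entries")
    if np.any(np.diag(w) != 0):
        raise ValueError("band matrix must have a zero diagonal")
    m = w.shape[0]
    off = ~np.eye(m, dtype=bool)
    if isinstance(threshold_theta, str):
        if threshold_theta != "median":
            raise ValueError(f"unknown threshold rule {threshold_theta!r}")
        theta = float(np.median(w[off]))
    else:
        theta = float(threshold_theta)
        if not 0.0 <= theta < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
    adj = (w > theta) & off
    return CausalNetwork(weights=w, threshold_theta=theta, binary_adj=adj)


def clustering_coefficient(net: CausalNetwork) -> float:
    """Directed binary clustering: for node i, e_i = |in-or-out neighbours|,
    c_i = (# ordered neighbour pairs (u, v) with edge u->v) / (e_i (e_i - 1)),
    defined 0 when e_i < 2; C is the mean of c_i over all nodes."""
    adj = net.binary_adj
    n = net.n_nodes
    und = adj | adj.T  # symmetric "is neighbour" relation
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(und[i] | und[:, i])[0]
        nbrs = nbrs[nbrs != i]
        e_i = len(nbrs)
        if e_i < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        # adj[v, u] is the directed edge u -> v; total count over ordered pairs
        c[i] = sub.sum() / (e_i * (e_i - 1))
    return float(c.mean())


def network_density(net: CausalNetwork) -> float:
    """Realised directed edges as a fraction of N(N-1) possible."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("network density requires at least 2 nodes")
    return net.n_edges / (n * (n - 1))


def global_efficiency(net: CausalNetwork) -> float:
    """Mean inverse directed shortest-path length over ordered node pairs.

    Edge lengths are 1 / (w / max(w)) on suprathreshold edges, so the
    strongest connection in the network has unit length; disconnected pairs
    contribute 0.  An edgeless network returns 0 with a warning.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    if net.n_edges == 0:
        warnings.warn("network has no suprathreshold edges; E_global defined as 0")
        return 0.0
    w_edges = np.where(net.binary_adj, net.weights, 0.0)
    w_max = w_edges.max()
    lengths = np.zeros_like(w_edges)
    lengths[net.binary_adj] = w_max / w_edges[net.binary_adj]
    # graph[u, v] = length of edge u -> v; our adjacency is sink-by-source
    graph = csr_matrix(lengths.T)
    dist = dijkstra(graph, directed=True)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    inv[finite] = 1.0 / dist[finite]
    return float(inv.sum() / (n * (n - 1)))


def network_metrics(
    band_matrix: np.ndarray, threshold_theta, band_label: str = ""
) -> NetworkMetrics:
    """Convenience wrapper: build the network and compute all three metrics."""
    net = build_network(band_matrix, threshold_theta)
    if net.n_edges == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e_glob = global_efficiency(net)
    else:
        e_glob = global_efficiency(net)
    return NetworkMetrics(
        C=clustering_coefficient(net),
        D=network_density(net),
        E_global=e_glob,
        band_label=band_label,
        threshold_theta=net.threshold_theta,
    )
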