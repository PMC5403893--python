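"""Minimum spanning tree of a PLI network and its topology metrics.

The MST is built with Kruskal's algorithm on edge costs 1/PLI, so the
strongest connections are retained as long as they close no cycle: the
tree minimizes the total inverse weight, equivalently maximizes total PLI
among spanning trees.  Because the MST depends only on the rank order of
the weights, it is invariant under any strictly increasing transform of
the PLI values.

Metric conventions (recorded in output metadata):

- betweenness centrality (BC): for node v, the number of unordered pairs
  (s, t), s != t != v, whose unique tree path passes through v, divided
  by (N-1)(N-2)/2 — the star center scores exactly 1.
- degree is also reported as a fraction of the 2(N-1) endpoint slots.
- eccentricity and diameter use hop counts within the tree.
- degree correlation R: Pearson correlation over edge-endpoint degree
  pairs, each edge contributing both orientations; undefined (NaN) when
  endpoint degrees have zero variance.
- kappa: the degree divergence <k^2>/<k>; the full degree histogram P(k)
  is retained alongside.
- tree hierarchy: Th = leaf_number / (2 * m * BC_max), m = N - 1 edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

BC_NORMALIZATION = "unordered pairs (N-1)(N-2)/2"
DEGREE_NORMALIZATION = "endpoint fraction degree/(2(N-1))"


@dataclass
class SpanningTree:
    """An N-node, (N-1)-edge acyclic connected subgraph.

    Edges store the original PLI weight (not the 1/PLI cost).
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )
        if any(w <= 0 for _, _, w in self.edges):
            raise ValueError("tree edge weights must be positive")
        g = self.to_networkx()
        if g.number_of_nodes() != self.n_nodes or not nx.is_connected(g):
            raise ValueError("edges do not form a connected spanning tree")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class MSTMetrics:
    """Scalar and per-node summaries of one spanning tree."""

    n_nodes: int
    degree: np.ndarray
    degree_fraction: np.ndarray
    bc: np.ndarray
    bc_max: float
    eccentricity: np.ndarray
    diameter: int
    leaf_number: int
    leaf_fraction: float
    degree_correlation_r: float
    kappa: float
    degree_histogram: dict[int, float]
    tree_hierarchy: float
    bc_normalization: str = BC_NORMALIZATION
    degree_normalization: str = DEGREE_NORMALIZATION


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(matrix: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Kruskal MST on costs 1/PLI; deterministic tie-breaking.

    Candidate edges are sorted by (1/weight, i, j) with i < j, so equal
    PLI values resolve to the lexicographically smallest node pair.

    Raises
    ------
    ValueError
        If the positive-weight graph is disconnected (lists components).
    """
    labels = matrix.roi_labels if isinstance(matrix, ConnectivityMatrix) else None
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("MST needs at least 2 nodes")
    pos = csr_matrix(np.where(w > 0, w, 0.0))
    n_comp, comp = connected_components(pos, directed=False)
    if n_comp > 1:
        groups = [
            [int(v) for v in np.flatnonzero(comp == c)]
            for c in range(n_comp)
        ]
        raise ValueError(
            f"graph disconnected at positive weights; components: {groups}"
        )
    candidates = sorted(
        (1.0 / w[i, j], i, j)
        for i in range(n - 1)
        for j in range(i + 1, n)
        if w[i, j] > 0
    )
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for _, i, j in candidates:
        if uf.union(i, j):
            edges.append((i, j, float(w[i, j])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n_nodes=n, edges=edges, roi_labels=labels)


def mst_degree(tree: SpanningTree) -> tuple[np.ndarray, np.ndarray]:
    """Raw degree per node and its fraction of the 2(N-1) endpoint slots."""
    deg = tree.degrees()
    return deg, deg / (2.0 * (tree.n_nodes - 1))


def mst_betweenness(tree: SpanningTree) -> np.ndarray:
    """Pair-normalized betweenness centrality of every node, in [0, 1]."""
    g = tree.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=True, weight=None)
    return np.array([bc[v] for v in range(tree.n_nodes)])


def mst_distance_metrics(tree: SpanningTree) -> tuple[np.ndarray, int]:
    """Hop-count eccentricity per node and the tree diameter."""
    g = tree.to_networkx()
    ecc = nx.eccentricity(g)
    ecc_arr = np.array([ecc[v] for v in range(tree.n_nodes)], dtype=int)
    return ecc_arr, int(ecc_arr.max())


def mst_leaf_number(tree: SpanningTree) -> int:
    return int(np.sum(tree.degrees() == 1))


def mst_degree_correlation(tree: SpanningTree) -> float:
    """Pearson correlation of endpoint degrees over both edge orientations.

    Returns NaN when either endpoint-degree margin has zero variance.
    """
    deg = tree.degrees()
    x = np.array(
        [deg[i] for i, j, _ in tree.edges] + [deg[j] for i, j, _ in tree.edges],
        dtype=float,
    )
    y = np.array(
        [deg[j] for i, j, _ in tree.edges] + [deg[i] for i, j, _ in tree.edges],
        dtype=float,
    )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mst_kappa(tree: SpanningTree) -> tuple[float, dict[int, float]]:
    """Degree divergence <k^2>/<k> and the degree histogram P(k)."""
    deg = tree.degrees().astype(float)
    kappa = float((deg**2).mean() / deg.mean())
    ks, counts = np.unique(deg.astype(int), return_counts=True)
    hist = {int(k): float(c) / tree.n_nodes for k, c in zip(ks, counts)}
    return kappa, hist


def mst_tree_hierarchy(tree: SpanningTree) -> float:
    """Th = leaf_number / (2 * m * BC_max): integration vs. hub overload."""
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy needs at least 3 nodes")
    bc_max = float(mst_betweenness(tree).max())
    if bc_max == 0.0:
        raise ValueError("degenerate tree: maximum betweenness is zero")
    m = tree.n_nodes - 1
    return mst_leaf_number(tree) / (2.0 * m * bc_max)


def mst_metrics(tree: SpanningTree) -> MSTMetrics:
    """Bundle the full MST metric suite for one tree."""
    deg, deg_frac = mst_degree(tree)
    bc = mst_betweenness(tree)
    ecc, diameter = mst_distance_metrics(tree)
    leaves = mst_leaf_number(tree)
    kappa, hist = mst_kappa(tree)
    return MSTMetrics(
        n_nodes=tree.n_nodes,
        degree=deg,
        degree_fraction=deg_frac,
        bc=bc,
        bc_max=float(bc.max()),
        eccentricity=ecc,
        diameter=diameter,
        leaf_number=leaves,
        leaf_fraction=leaves / (tree.n_nodes - 1.0),
        degree_correlation_r=mst_degree_correlation(tree),
        kappa=kappa,
        degree_histogram=hist,
        tree_hierarchy=mst_tree_hierarchy(tree),
    )
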