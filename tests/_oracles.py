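"""Independent brute-force oracles used to pin the graph/statistics code.

Everything here works by direct enumeration (Prüfer sequences, BFS path
reconstruction, step-up rule applied literally) and deliberately shares
no code with the package implementation.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence into the edge list of a labeled tree."""
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def all_spanning_trees(n: int):
    """Yield the edge lists of all n^(n-2) labeled trees on n nodes."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield prufer_to_edges(seq, n)


def random_tree(rng: np.random.Generator, n: int) -> list[tuple[int, int]]:
    if n == 2:
        return [(0, 1)]
    seq = tuple(rng.integers(0, n, size=n - 2))
    return prufer_to_edges(seq, n)


def _adjacency(edges, n):
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def tree_path(edges, n, s, t) -> list[int]:
    """The unique path between s and t, found by BFS with parents."""
    adj = _adjacency(edges, n)
    parent = {s: None}
    queue = [s]
    while queue:
        u = queue.pop(0)
        if u == t:
            break
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                queue.append(v)
    path = [t]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def bf_betweenness_counts(edges, n) -> np.ndarray:
    """Raw pass-through pair counts per node by explicit path enumeration."""
    counts = np.zeros(n, dtype=int)
    for s in range(n):
        for t in range(s + 1, n):
            for v in tree_path(edges, n, s, t)[1:-1]:
                counts[v] += 1
    return counts


def bf_eccentricity(edges, n) -> np.ndarray:
    ecc = np.zeros(n, dtype=int)
    for v in range(n):
        ecc[v] = max(
            len(tree_path(edges, n, v, t)) - 1 for t in range(n) if t != v
        )
    return ecc


def bf_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def bf_bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * m / (rank_from_top + 1))
        adj[idx] = running_min
    return adj


def bf_shortest_distance(weights: np.ndarray, s: int, t: int) -> float:
    """Shortest 1/w path distance by enumerating all simple paths."""
    n = weights.shape[0]
    best = np.inf
    others = [v for v in range(n) if v not in (s, t)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            nodes = (s, *mid, t)
            d = 0.0
            for a, b in zip(nodes[:-1], nodes[1:]):
                if weights[a, b] <= 0:
                    d = np.inf
                    break
                d += 1.0 / weights[a, b]
            best = min(best, d)
    return best
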