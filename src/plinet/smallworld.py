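"""Weighted small-world metrics with surrogate normalization.

Weighted clustering coefficient (Cw), per node i:

    Cw_i = sum_{k != l} w_ik * w_il * w_kl  /  sum_{k != l} w_ik * w_il

(0 when the denominator vanishes), averaged over nodes.  Note this ratio
is *not* scale free: Cw(c*W) = c * Cw(W).

Weighted characteristic path length (Lw), with distances d_ij = 1/w_ij
(infinite for absent edges) and shortest-path lengths L_ij, uses the
harmonic-mean form that tolerates disconnected pairs:

    Lw = 1 / [ (1/(N(N-1))) * sum_{i != j} 1/L_ij ],  1/L_ij = 0 if i,j disconnected

so Lw(c*W) = Lw(W)/c.

Both observed values are divided by their means over random surrogate
networks obtained by shuffling the off-diagonal weights while keeping the
matrix symmetric — preserving the weight multiset but destroying topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix


def _as_weights(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else matrix
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class SmallWorldMetrics:
    cw: float
    lw: float
    cw_random_mean: float
    lw_random_mean: float
    normalized_cw: float
    normalized_lw: float
    n_surrogates: int


def weighted_clustering(matrix: ConnectivityMatrix | np.ndarray) -> float:
    w = _as_weights(matrix)
    strength = w.sum(axis=1)
    # ordered-pair sums: numerator_i = (W^3)_ii, denominator_i = s_i^2 - (W^2)_ii
    numer = np.diag(w @ w @ w)
    denom = strength**2 - (w**2).sum(axis=1)
    terms = np.divide(numer, denom, out=np.zeros_like(numer), where=denom > 0)
    return float(terms.mean())


def weighted_path_length(matrix: ConnectivityMatrix | np.ndarray) -> float:
    w = _as_weights(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    inv = np.zeros_like(w)
    nz = w > 0
    inv[nz] = 1.0 / w[nz]
    dist = shortest_path(csr_matrix(inv), directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv_dist = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    efficiency = inv_dist[off].mean()
    if efficiency == 0.0:
        raise ValueError("graph fully disconnected: Lw is infinite")
    return float(1.0 / efficiency)


def shuffle_surrogate(
    matrix: ConnectivityMatrix | np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Random symmetric surrogate: permute the upper-triangle weights."""
    w = _as_weights(matrix)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    iu = np.triu_indices_from(w, k=1)
    vals = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = vals
    out += out.T
    return out


def normalized_metrics(
    matrix: ConnectivityMatrix | np.ndarray,
    n_surrogates: int = 50,
    seed: int | np.random.Generator | None = None,
) -> SmallWorldMetrics:
    """Observed Cw/Lw divided by their means over shuffled surrogates."""
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    w = _as_weights(matrix)
    cw = weighted_clustering(w)
    lw = weighted_path_length(w)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cws = np.empty(n_surrogates)
    lws = np.empty(n_surrogates)
    for k in range(n_surrogates):
        s = shuffle_surrogate(w, rng)
        cws[k] = weighted_clustering(s)
        lws[k] = weighted_path_length(s)
    # the mean of identical values is that value; bypass summation rounding
    # so shuffle-invariant (constant-weight) inputs normalize to exactly 1
    cw_rand = float(cws[0]) if np.all(cws == cws[0]) else float(cws.mean())
    lw_rand = float(lws[0]) if np.all(lws == lws[0]) else float(lws.mean())
    if cw_rand == 0.0:
        raise ValueError("degenerate weights: surrogate mean Cw is zero")
    return SmallWorldMetrics(
        cw=cw,
        lw=lw,
        cw_random_mean=cw_rand,
        lw_random_mean=lw_rand,
        normalized_cw=cw / cw_rand,
        normalized_lw=lw / lw_rand,
        n_surrogates=n_surrogates,
    )
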