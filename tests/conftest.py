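from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plinet import SpanningTree

from _oracles import random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pli_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric matrix of strictly positive PLI-like weights."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
    w += w.T
    return w


def random_spanning_tree(rng: np.random.Generator, n: int) -> SpanningTree:
    edges = [
        (min(i, j), max(i, j), float(rng.uniform(0.1, 1.0)))
        for i, j in random_tree(rng, n)
    ]
    return SpanningTree(n_nodes=n, edges=edges)


def star_tree(n: int) -> SpanningTree:
    return SpanningTree(
        n_nodes=n, edges=[(0, j, 0.5) for j in range(1, n)]
    )


def path_tree(n: int) -> SpanningTree:
    return SpanningTree(
        n_nodes=n, edges=[(j, j + 1, 0.5) for j in range(n - 1)]
    )
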