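"""Independent brute-force oracles used to check the fast implementations.

Everything here deliberately avoids the library's own code paths: shortest
paths come from exhaustive enumeration of simple paths over existing edges,
and efficiencies are literal transcriptions of the defining formulas
evaluated with those enumerated distances.  Only usable for tiny graphs.
"""

from __future__ import annotations

import numpy as np


def enumerate_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by exhaustive simple-path enumeration.

    Edge lengths are 1/weight.  Every simple path between every ordered pair
    is walked; no pruning beyond the simple-path constraint.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    adj = [np.flatnonzero(W[i] > 0) for i in range(n)]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)

    def dfs(node: int, source: int, visited: list[bool], dist: float) -> None:
        for nxt in adj[node]:
            if visited[nxt]:
                continue
            d = dist + L[node, nxt]
            if d < D[source, nxt]:
                D[source, nxt] = d
            visited[nxt] = True
            dfs(nxt, source, visited, d)
            visited[nxt] = False

    for s in range(n):
        visited = [False] * n
        visited[s] = True
        dfs(s, s, visited, 0.0)
    return D


def nodal_eglob_oracle(W: np.ndarray, binary: bool) -> np.ndarray:
    """Nodal global efficiency from the enumerated distances."""
    W = np.asarray(W, dtype=float)
    if binary:
        W = (W > 0).astype(float)
    n = W.shape[0]
    D = enumerate_shortest_paths(W)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
        out[i] = acc / (n - 1)
    return out


def nodal_eloc_oracle(W: np.ndarray, binary: bool) -> np.ndarray:
    """Nodal local efficiency, literal formula with enumerated subgraph distances."""
    W = np.asarray(W, dtype=float)
    if binary:
        W = (W > 0).astype(float)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = enumerate_shortest_paths(sub)
        acc = 0.0
        for j in range(k):
            for h in range(k):
                if j == h or not np.isfinite(D[j, h]) or D[j, h] <= 0:
                    continue
                if binary:
                    acc += 1.0 / D[j, h]
                else:
                    acc += (W[i, nbrs[j]] * W[i, nbrs[h]] / D[j, h]) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def random_graph(rng: np.random.Generator, n: int, density: float, binary: bool) -> np.ndarray:
    """Random symmetric zero-diagonal weight matrix."""
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < density:
                W[a, b] = W[b, a] = 1.0 if binary else rng.uniform(0.05, 1.0)
    return W
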