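"""Binary and weighted global and local network efficiency.

Connection weights are mapped to lengths by elementwise reciprocal (strong
connections are short); shortest path lengths come from Dijkstra's algorithm
per source node.  Nodal global efficiency of node *i* is the mean inverse
shortest-path length from *i* to every other node (1/inf = 0 for unreachable
pairs):

    E_glob(i) = (1/(n-1)) * sum_{j != i} 1 / d(i, j)

Binary nodal local efficiency is the global efficiency of the subgraph
induced by *i*'s neighbours; the weighted form uses the cube-root
combination of the two stem weights with the inverse neighbour-subgraph
distance:

    E_loc(i) = sum_{j != h in N(i)} (w_ij * w_ih / d_jh(N(i)))^(1/3) / (k_i (k_i - 1))

with E_loc(i) = 0 when node *i* has fewer than two neighbours.  Whole-brain
values are unweighted arithmetic means of the nodal vectors over all nodes,
including isolated ones (which score 0 but keep their slot so node indexing
stays stable across subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import ConnectivityMatrix, EfficiencyResult, Weighting

__all__ = [
    "LengthMatrix",
    "weight_to_length",
    "shortest_paths",
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "summarize",
]


@dataclass
class LengthMatrix:
    """Inverse-weight connection lengths; +inf marks absent connections."""

    lengths: np.ndarray
    derivation: str = "inverse-weight"


def weight_to_length(M: ConnectivityMatrix | np.ndarray) -> LengthMatrix:
    """Elementwise reciprocal on nonzero weights; zeros become +inf."""
    W = M.weights if isinstance(M, ConnectivityMatrix) else np.asarray(M, dtype=float)
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    return LengthMatrix(L)


def shortest_paths(L: LengthMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by Dijkstra; +inf when unreachable."""
    lengths = L.lengths if isinstance(L, LengthMatrix) else np.asarray(L, dtype=float)
    finite = np.isfinite(lengths)
    np.fill_diagonal(finite, False)
    graph = csr_matrix((lengths[finite], np.nonzero(finite)), shape=lengths.shape)
    return dijkstra(graph, directed=False)


def _lengths_for(M: ConnectivityMatrix) -> np.ndarray:
    if M.weighting is Weighting.BINARY:
        W = (M.weights > 0).astype(float)
    else:
        W = M.weights
    return weight_to_length(W).lengths


def nodal_global_efficiency(M: ConnectivityMatrix) -> np.ndarray:
    """Nodal global efficiency vector (length n)."""
    n = M.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = shortest_paths(_lengths_for(M))
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_local_efficiency(M: ConnectivityMatrix) -> np.ndarray:
    """Nodal local efficiency vector (length n); 0 for nodes of degree < 2."""
    W = M.weights
    n = M.n_nodes
    A = W > 0
    out = np.zeros(n)
    binary = M.weighting is Weighting.BINARY
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        if binary:
            D = shortest_paths(weight_to_length((sub > 0).astype(float)).lengths)
        else:
            D = shortest_paths(weight_to_length(sub).lengths)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
        np.fill_diagonal(inv_d, 0.0)
        if binary:
            out[i] = inv_d.sum() / (k * (k - 1))
        else:
            stems = W[i, nbrs]
            out[i] = np.cbrt(np.outer(stems, stems) * inv_d).sum() / (k * (k - 1))
    return out


def summarize(M: ConnectivityMatrix) -> EfficiencyResult:
    """Nodal efficiency vectors and their whole-brain (mean) values."""
    eg = nodal_global_efficiency(M)
    el = nodal_local_efficiency(M)
    return EfficiencyResult(
        nodal_eglob=eg,
        nodal_eloc=el,
        wholebrain_eglob=float(eg.mean()),
        wholebrain_eloc=float(el.mean()),
        weighting=M.weighting,
    )
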