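"""Intra-domain geometry: kNN-graph geodesics, distance scaling, PCA plumbing.

The Gromov-Wasserstein term compares datasets through intra-domain distance
matrices.  Following common practice for single-cell embeddings, distances
are geodesics (all-pairs shortest paths) on a symmetrized k-nearest-neighbor
graph with Euclidean edge weights, which tracks the data manifold rather than
straight-line distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .ot_core import DimensionError, DomainError

__all__ = ["DistanceMatrix", "knn_geodesic", "normalize_distances", "reduce_pca"]

logger = logging.getLogger(__name__)

# Sentinel weight for zero-length edges (duplicate points): keeps the edge in
# the sparse structure, contributes nothing measurable to path lengths.
_ZERO_EDGE = 1e-300


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative all-pairs distance matrix with zero diagonal."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise DomainError("distance matrix must be finite")
        if np.any(v < 0):
            raise DomainError("distances must be nonnegative")
        if np.max(np.abs(v - v.T)) > 1e-12 * max(1.0, np.max(np.abs(v))):
            raise DomainError("distance matrix must be symmetric")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def knn_geodesic(X, k: int, weighted: bool = True) -> DistanceMatrix:
    """Geodesic distances on the symmetrized kNN graph of ``X``.

    The graph is the union of directed kNN edges (an edge exists if i is
    among j's neighbors OR j among i's), weighted by Euclidean distance
    (``weighted=False`` uses unit weights instead).  If the graph is
    disconnected, components are reconnected by adding, for each edge of a
    minimum-spanning-tree over components (component-pair weights = shortest
    Euclidean link), the corresponding single shortest Euclidean edge; a
    warning is logged.

    Parameters
    ----------
    X : array_like, shape (n, d)
        Sample coordinates.
    k : int
        Number of neighbors, ``1 <= k < n``.
    weighted : bool
        Euclidean edge weights (default) or unweighted hop counts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D sample matrix")
    if not np.all(np.isfinite(X)):
        raise DomainError("X must be finite")
    n = X.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n = {n}, got {k}")

    # sklearn returns each point among its own neighbors; request one extra
    # and skip the self entry while collecting k true neighbors.
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    dist, idx = nn.kneighbors(X)
    rows, cols, vals = [], [], []
    for i in range(n):
        taken = 0
        for j_pos in range(idx.shape[1]):
            j = idx[i, j_pos]
            if j == i:
                continue
            rows.append(i)
            cols.append(j)
            w = dist[i, j_pos] if weighted else 1.0
            vals.append(w if w > 0 else _ZERO_EDGE)
            taken += 1
            if taken == k:
                break
    W = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union symmetrization

    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        logger.warning(
            "kNN graph with k=%d has %d components; repairing connectivity", k, n_comp
        )
        W = _repair_connectivity(W, X, labels, n_comp, weighted)

    D = shortest_path(W, method="D", directed=False)
    if not np.all(np.isfinite(D)):
        raise DomainError("geodesic matrix still contains infinities after repair")
    D[D < 10 * _ZERO_EDGE] = 0.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(0.5 * (D + D.T))


def _repair_connectivity(W, X, labels, n_comp, weighted):
    """Join components along an MST of shortest Euclidean inter-component links."""
    comp_members = [np.flatnonzero(labels == c) for c in range(n_comp)]
    # best point-pair per component pair
    best = {}
    for a in range(n_comp):
        for b in range(a + 1, n_comp):
            da = cdist(X[comp_members[a]], X[comp_members[b]])
            ia, ib = np.unravel_index(np.argmin(da), da.shape)
            best[(a, b)] = (float(da[ia, ib]), comp_members[a][ia], comp_members[b][ib])
    from scipy.sparse.csgraph import minimum_spanning_tree

    meta = np.zeros((n_comp, n_comp))
    for (a, b), (w, _, _) in best.items():
        meta[a, b] = w if w > 0 else _ZERO_EDGE
    mst = minimum_spanning_tree(csr_matrix(meta)).tocoo()
    W = W.tolil()
    for a, b in zip(mst.row, mst.col):
        key = (min(a, b), max(a, b))
        w, i, j = best[key]
        wij = (w if w > 0 else _ZERO_EDGE) if weighted else 1.0
        W[i, j] = wij
        W[j, i] = wij
    return W.tocsr()


def normalize_distances(D: DistanceMatrix) -> DistanceMatrix:
    """Scale a distance matrix so its maximum is exactly 1.

    Makes the entropic weight eps comparable across domains with different
    raw scales.  An all-zero matrix is returned unchanged with a warning.
    """
    mx = float(np.max(D.values))
    if mx <= 0:
        logger.warning("normalize_distances: all-zero distance matrix, left unchanged")
        return D
    return DistanceMatrix(D.values / mx)


def reduce_pca(X, n_components: int):
    """Project centered data onto its top principal components.

    Components are ordered by decreasing explained variance and sign-fixed so
    that each component's largest-magnitude loading is positive, making the
    output deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not (1 <= n_components <= min(n, d)):
        raise ValueError(
            f"n_components must be in [1, min(n, d)] = [1, {min(n, d)}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    comps = pca.components_
    signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    return Z * signs[None, :]
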