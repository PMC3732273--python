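"""Non-linear embeddings of an atlas library from its distance matrix.

Three spectral techniques are implemented directly on the pairwise distance
matrix (the library lives in a metric space, not a coordinate space):

Isomap
    All-pairs shortest paths on the k_D-nearest-neighbour graph approximate
    geodesic distances on the manifold; classical multidimensional scaling of
    the squared geodesics yields coordinates whose Euclidean distances
    reproduce the geodesics.

Locally Linear Embedding (LLE)
    Each atlas is reconstructed as an affine combination of its k_D nearest
    neighbours; the weights that minimise the reconstruction error (a local
    least-squares problem) are found from a local Gram matrix built from
    distances alone, and the embedding is read off the bottom eigenvectors of
    (I - W)^T (I - W).

Laplacian Eigenmaps (LEM)
    Heat-kernel weights W_ij = exp(-D_ij^2 / t) on graph edges; the embedding
    solves the generalized eigenproblem L f = lambda Deg f with L = Deg - W,
    discarding the constant eigenvector at eigenvalue ~0.

All three require a *connected* k_D-nearest-neighbour graph; a disconnected
graph raises :class:`~atlasmanifold.errors.DisconnectedGraphError` rather
than silently restricting to a component.

Determinism: neighbour ties are broken by smaller index, and each coordinate
column's sign is fixed so that its largest-magnitude entry is positive, so
re-running on identical input reproduces the embedding bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import DisconnectedGraphError, SingularLocalSystemError
from .metric import DistanceMatrix

__all__ = [
    "NeighbourGraph",
    "Embedding",
    "build_knn_graph",
    "assert_connected",
    "embed_isomap",
    "embed_lle",
    "embed_lem",
    "compute_embedding",
]

TECHNIQUES = ("isomap", "lle", "lem")


@dataclass(frozen=True)
class NeighbourGraph:
    """Weighted k_D-nearest-neighbour graph over the atlas library."""

    n: int
    k_D: int
    mask: np.ndarray  # boolean symmetric adjacency, no self-edges
    weights: np.ndarray  # metric distance on edges, 0 elsewhere
    knn_indices: np.ndarray  # (n, k_D) each node's own nearest neighbours
    symmetrization: str
    ids: tuple
    distances: "DistanceMatrix" = None  # the matrix the graph was built from

    def degree(self) -> np.ndarray:
        return self.mask.sum(axis=1)


def _knn_indices(D: np.ndarray, k_D: int) -> np.ndarray:
    """Each row's k_D nearest other points, ties broken by smaller index."""
    n = D.shape[0]
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")
    return order[:, :k_D]


def build_knn_graph(D: DistanceMatrix, k_D: int, symmetrization: str = "union") -> NeighbourGraph:
    """Build the k_D-nearest-neighbour graph from a distance matrix.

    ``union`` keeps an edge if either endpoint lists the other among its k_D
    nearest (so every node retains all of its own k_D nearest neighbours);
    ``mutual`` requires both.
    """
    n = D.n
    if not 1 <= k_D <= n - 1:
        raise ValueError(f"k_D must be in [1, {n - 1}], got {k_D}")
    if symmetrization not in ("union", "mutual"):
        raise ValueError("symmetrization must be 'union' or 'mutual'")
    knn = _knn_indices(D.values, k_D)
    directed = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_D)
    directed[rows, knn.ravel()] = True
    mask = (directed | directed.T) if symmetrization == "union" else (directed & directed.T)
    np.fill_diagonal(mask, False)
    weights = np.where(mask, D.values, 0.0)
    return NeighbourGraph(
        n=n,
        k_D=k_D,
        mask=mask,
        weights=weights,
        knn_indices=knn,
        symmetrization=symmetrization,
        ids=D.ids,
        distances=D,
    )


def assert_connected(g: NeighbourGraph) -> np.ndarray:
    """Return per-node component labels; raise if there is more than one."""
    n_comp, labels = connected_components(csr_matrix(g.mask), directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(labels, n_comp)
    return labels


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if V.size == 0:
        return V
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class Embedding:
    """Low-dimensional manifold coordinates plus spectral byproducts.

    ``cache`` holds whatever the matching out-of-sample extension needs:
    geodesic matrix and MDS eigenpairs (isomap), neighbour sets and the
    regularization used (lle), or kernel bandwidth, degrees and eigenpairs
    (lem).  ``distances`` keeps the training distance matrix so a target can
    be related to the training points without touching any displacement
    field again.
    """

    technique: str
    coords: np.ndarray  # (n, d)
    d: int
    eigenvalues: np.ndarray
    ids: tuple
    graph: NeighbourGraph
    distances: DistanceMatrix
    cache: Dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _geodesic_matrix(g: NeighbourGraph) -> np.ndarray:
    from scipy.sparse.csgraph import csgraph_from_dense

    assert_connected(g)
    dense = np.where(g.mask, g.weights, np.inf)
    np.fill_diagonal(dense, 0.0)
    # null_value=inf keeps exact-zero edge weights (duplicate atlases) alive.
    geo = shortest_path(csgraph_from_dense(dense, null_value=np.inf), method="D", directed=False)
    if np.isinf(geo).any():  # pragma: no cover - guarded by assert_connected
        raise DisconnectedGraphError(np.zeros(g.n, dtype=int), 2)
    return geo


def embed_isomap(g: NeighbourGraph, d: int) -> Embedding:
    """Geodesic-preserving embedding via classical MDS of graph geodesics."""
    n = g.n
    if not 1 <= d <= n - 1:
        raise ValueError(f"d must be in [1, {n - 1}], got {d}")
    geo = _geodesic_matrix(g)
    G2 = geo**2
    col_mean = G2.mean(axis=0)
    grand_mean = float(G2.mean())
    B = -0.5 * (G2 - col_mean[None, :] - col_mean[:, None] + grand_mean)
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam, kind="stable")[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = max(1.0, abs(lam[0])) * 1e-12
    n_pos = int((lam > tol).sum())
    if d > n_pos:
        warnings.warn(
            f"isomap: only {n_pos} positive eigenvalues available, truncating d from {d}",
            RuntimeWarning,
        )
        d = n_pos
    vec = _fix_signs(vec[:, :d])
    lam = lam[:d]
    coords = vec * np.sqrt(lam)[None, :]
    return Embedding(
        technique="isomap",
        coords=coords,
        d=d,
        eigenvalues=lam,
        ids=g.ids,
        graph=g,
        distances=g.distances,
        cache={
            "geodesics": geo,
            "col_mean_sq": G2.mean(axis=0),
            "grand_mean_sq": grand_mean,
            "eigvecs": vec,
            "eigvals": lam,
        },
    )


def lle_weights(
    d_point_to_nbrs: np.ndarray, D_nbrs: np.ndarray, reg: float
) -> np.ndarray:
    """Affine reconstruction weights of a point from its neighbours.

    Works purely on distances: the local Gram matrix is
    C_jk = 0.5 * (d_j^2 + d_k^2 - D_jk^2), which equals
    <x_j - x, x_k - x> whenever the distances are Euclidean.  C is
    regularized by ``reg * trace(C)`` and solved through its
    eigendecomposition (stable when C is rank-deficient, as happens for
    points on a low-dimensional patch).  A neighbour at exactly zero
    distance *is* the point, and receives all the weight.
    """
    k = len(d_point_to_nbrs)
    zero = np.flatnonzero(d_point_to_nbrs == 0.0)
    if zero.size:
        w = np.zeros(k)
        w[zero[0]] = 1.0
        return w
    d2 = d_point_to_nbrs**2
    C = 0.5 * (d2[:, None] + d2[None, :] - D_nbrs**2)
    C = 0.5 * (C + C.T)
    tr = np.trace(C)
    alpha = reg * tr if tr > 0 else reg
    lam, V = np.linalg.eigh(C)
    lam = np.clip(lam, 0.0, None) + alpha
    ones = np.ones(k)
    w = V @ ((V.T @ ones) / lam)
    s = w.sum()
    if not np.isfinite(s) or s == 0.0:
        raise SingularLocalSystemError("local LLE system singular even after regularization")
    return w / s


def embed_lle(D: DistanceMatrix, k_D: int, d: int, reg: float = 1e-3) -> Embedding:
    """Locally linear embedding computed from the distance matrix alone."""
    n = D.n
    if not 1 <= d <= n - 2:
        raise ValueError(f"d must be in [1, {n - 2}], got {d}")
    g = build_knn_graph(D, k_D, symmetrization="union")
    assert_connected(g)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = g.knn_indices[i]
        w = lle_weights(D.values[i, nbrs], D.values[np.ix_(nbrs, nbrs)], reg)
        W[i, nbrs] = w
    M = np.eye(n) - W
    M = M.T @ M
    lam, vec = np.linalg.eigh(M)
    # lam[0] ~ 0 with a constant eigenvector: the trivial solution, discarded.
    vec = _fix_signs(vec[:, 1 : 1 + d])
    return Embedding(
        technique="lle",
        coords=vec,
        d=d,
        eigenvalues=lam[1 : 1 + d],
        ids=D.ids,
        graph=g,
        distances=D,
        cache={"weights": W, "reg": reg, "trivial_eigenvalue": float(lam[0])},
    )


def embed_lem(g: NeighbourGraph, d: int, t: float = 1.0, weighting: str = "heat") -> Embedding:
    """Laplacian-eigenmaps embedding of the neighbour graph.

    ``weighting='heat'`` uses W_ij = exp(-D_ij^2 / t) on edges (t is the
    kernel bandwidth); ``'binary'`` uses W_ij = 1 on edges.
    """
    n = g.n
    if not 1 <= d <= n - 1:
        raise ValueError(f"d must be in [1, {n - 1}], got {d}")
    if weighting not in ("heat", "binary"):
        raise ValueError("weighting must be 'heat' or 'binary'")
    if weighting == "heat" and t <= 0:
        raise ValueError(f"kernel bandwidth t must be positive, got {t}")
    assert_connected(g)
    if weighting == "heat":
        W = np.where(g.mask, np.exp(-(g.weights**2) / t), 0.0)
    else:
        W = g.mask.astype(float)
    deg = W.sum(axis=1)
    Deg = np.diag(deg)
    L = Deg - W
    lam, vec = scipy.linalg.eigh(L, Deg)
    trivial = float(lam[0])
    if trivial > 1e-9:
        raise DisconnectedGraphError(np.zeros(n, dtype=int), 2)
    f = _fix_signs(vec[:, 1 : 1 + d])
    eigvals = lam[1 : 1 + d]
    return Embedding(
        technique="lem",
        coords=f,
        d=d,
        eigenvalues=eigvals,
        ids=g.ids,
        graph=g,
        distances=g.distances,
        cache={
            "t": t,
            "weighting": weighting,
            "degrees": deg,
            "eigvecs": f,
            "kernel_eigvals": 1.0 - eigvals,
            "trivial_eigenvalue": trivial,
            "trivial_eigvec": vec[:, 0],
        },
    )


def compute_embedding(
    technique: str,
    D: DistanceMatrix,
    d: int,
    k_D: int,
    t: float = 1.0,
    reg: float = 1e-3,
) -> Embedding:
    """Dispatch to the requested embedding technique."""
    if technique == "isomap":
        return embed_isomap(build_knn_graph(D, k_D), d)
    if technique == "lle":
        return embed_lle(D, k_D, d, reg=reg)
    if technique == "lem":
        return embed_lem(build_knn_graph(D, k_D), d, t=t)
    raise ValueError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
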