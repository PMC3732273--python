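"""Nyström out-of-sample extension of a learned manifold.

A new target image is placed on a precomputed embedding using only the
vector of metric distances between the target and the training atlases
(one registration to the average atlas, one subtraction of fields).  No
eigendecomposition is re-run and no displacement field is touched here.

Technique-specific rules:

isomap
    Approximate target-to-training geodesics through the target's k_D
    nearest training points acting as gateways into the graph, then apply
    the kernel-MDS Nyström formula
    y_k = (1/(2*sqrt(lambda_k))) * sum_j v_jk * (colmean_j(G^2) - geo(t,j)^2),
    which reproduces training coordinates exactly.

lle
    Reconstruction weights of the target from its k_D nearest training
    points (same local Gram and regularization as training), then the
    weighted combination of their embedded coordinates.

lem
    Kernel row K_j = exp(-dists_j^2 / t) over the target's k_D nearest
    training points, normalized by the target's own kernel degree, projected
    on the stored eigenvectors and divided by the kernel-form eigenvalues
    (1 - lambda_k).

A target at *exactly* zero metric distance from a training atlas is that
atlas, and receives its coordinates directly (see docs/methods.md for why
the kernel-row formula cannot reproduce this limit for LEM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtensionError
from .manifold import Embedding, lle_weights

__all__ = ["TargetEmbedding", "extend", "nearest_on_manifold"]


@dataclass(frozen=True)
class TargetEmbedding:
    coords: np.ndarray  # (d,)
    technique: str
    target_id: str = "target"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(c).all():
            raise ValueError("target coordinates are non-finite")
        object.__setattr__(self, "coords", c)


def _target_knn(dists: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(dists, kind="stable")
    return order[:k]


def extend(
    e: Embedding,
    dists: np.ndarray,
    target_id: str = "target",
    gateways: str = "knn",
    exact_match_tol: float = 0.0,
) -> TargetEmbedding:
    """Embed a target from its distance vector to the training atlases.

    ``dists`` must be computed with the same metric variant as the
    embedding's training distance matrix.  ``gateways`` controls which
    training points anchor the target's approximate geodesics for isomap
    (``'knn'``: its k_D nearest, mirroring graph construction; ``'all'``:
    every training point).
    """
    dists = np.asarray(dists, dtype=np.float64)
    n = e.n
    if dists.shape != (n,):
        raise ValueError(f"expected a length-{n} distance vector, got shape {dists.shape}")
    if not np.isfinite(dists).all() or (dists < 0).any():
        raise ValueError("target distances must be finite and non-negative")
    if gateways not in ("knn", "all"):
        raise ValueError("gateways must be 'knn' or 'all'")

    exact = np.flatnonzero(dists <= exact_match_tol)
    if exact.size:
        return TargetEmbedding(coords=e.coords[exact[0]].copy(), technique=e.technique, target_id=target_id)

    k_D = e.graph.k_D
    if e.technique == "isomap":
        geo = e.cache["geodesics"]
        gw = np.arange(n) if gateways == "all" else _target_knn(dists, k_D)
        geo_t = (dists[gw, None] + geo[gw, :]).min(axis=0)
        lam = e.cache["eigvals"]
        vec = e.cache["eigvecs"]
        coords = ((e.cache["col_mean_sq"] - geo_t**2) @ vec) / (2.0 * np.sqrt(lam))
    elif e.technique == "lle":
        nbrs = _target_knn(dists, k_D)
        D = e.distances.values
        w = lle_weights(dists[nbrs], D[np.ix_(nbrs, nbrs)], e.cache["reg"])
        coords = w @ e.coords[nbrs]
    elif e.technique == "lem":
        nbrs = _target_knn(dists, k_D)
        t = e.cache["t"]
        if e.cache["weighting"] == "heat":
            K = np.exp(-(dists[nbrs] ** 2) / t)
        else:
            K = np.ones(len(nbrs))
        deg_t = K.sum()
        if deg_t == 0.0:
            raise ExtensionError(
                "target kernel row is identically zero: the target is too far "
                "from every training atlas at this bandwidth"
            )
        lam_k = e.cache["kernel_eigvals"]
        if np.any(lam_k <= 1e-12):
            raise ExtensionError("kernel-form eigenvalue vanishes; cannot extend")
        f = e.cache["eigvecs"]
        coords = ((K / deg_t) @ f[nbrs]) / lam_k
    else:  # pragma: no cover
        raise ValueError(f"unknown technique {e.technique!r}")
    return TargetEmbedding(coords=coords, technique=e.technique, target_id=target_id)


def nearest_on_manifold(e: Embedding, t: TargetEmbedding, k_d: int) -> list:
    """Ids of the k_d training atlases nearest to the target on the manifold.

    Euclidean (L2) distance in embedding coordinates, ascending, ties broken
    by smaller training index.
    """
    if t.technique != e.technique:
        raise ValueError(f"target embedded with {t.technique!r}, manifold is {e.technique!r}")
    if not 1 <= k_d <= e.n:
        raise ValueError(f"k_d must be in [1, {e.n}], got {k_d}")
    diff = e.coords - t.coords[None, :]
    d2 = np.einsum("ij,ij->i", diff, diff)
    order = np.argsort(d2, kind="stable")[:k_d]
    return [e.ids[i] for i in order]
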