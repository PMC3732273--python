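"""Deformation-field distance between images.

Every image (atlas or target) is represented by the displacement field of
the non-rigid transformation relating it to a common average atlas, so the
distance between two images never requires a direct registration between
them.  Two variants of the voxel-wise comparison are provided:

``rms``
    sqrt( (1/N) * sum_x ||u_a(x) - u_b(x)||^2 ), the root-mean-square of the
    voxel-wise difference magnitudes.  This is the Euclidean distance between
    the flattened fields scaled by 1/sqrt(N), which makes downstream local
    Gram constructions (LLE) exact.  Default.

``mean_magnitude``
    (1/N) * sum_x ||u_a(x) - u_b(x)||, the mean difference magnitude.

Both are norm-induced, hence true metrics (symmetry, zero self-distance,
triangle inequality).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .volume_io import AtlasLibrary, DisplacementField

__all__ = ["VARIANTS", "field_distance", "distance_matrix", "target_distances", "DistanceMatrix"]

VARIANTS = ("rms", "mean_magnitude")


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown metric variant {variant!r}; choose from {VARIANTS}")


def field_distance(u_a: DisplacementField, u_b: DisplacementField, variant: str = "rms") -> float:
    """Distance (mm) between two images from their displacement fields."""
    _check_variant(variant)
    u_a.grid.require_match(u_b.grid)
    diff = u_a.vectors - u_b.vectors
    sq = np.einsum("...k,...k->...", diff, diff)
    if variant == "rms":
        return float(np.sqrt(sq.mean()))
    return float(np.sqrt(sq).mean())


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise deformation distances (mm)."""

    values: np.ndarray
    ids: tuple
    variant: str = "rms"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} ids")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        _check_variant(self.variant)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, indices: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return DistanceMatrix(
            values=self.values[np.ix_(idx, idx)],
            ids=tuple(self.ids[i] for i in idx),
            variant=self.variant,
        )

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.index.name = f"variant={self.variant}"
        df.to_csv(os.fspath(path), sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, os.PathLike]) -> "DistanceMatrix":
        df = pd.read_csv(os.fspath(path), sep="\t", index_col=0)
        variant = "rms"
        if df.index.name and "=" in str(df.index.name):
            variant = str(df.index.name).split("=", 1)[1]
        return cls(values=df.to_numpy(dtype=float), ids=tuple(df.columns), variant=variant)


def distance_matrix(library: AtlasLibrary, variant: str = "rms") -> DistanceMatrix:
    """Pairwise distances between all library entries."""
    _check_variant(variant)
    n = len(library)
    if n < 2:
        raise ValueError("need at least 2 library entries")
    fields = library.fields_array()
    values = np.zeros((n, n))
    for i in range(n - 1):
        diff = fields[i + 1 :] - fields[i]
        sq = np.einsum("...k,...k->...", diff, diff).reshape(n - i - 1, -1)
        if variant == "rms":
            row = np.sqrt(sq.mean(axis=1))
        else:
            row = np.sqrt(sq).mean(axis=1)
        values[i, i + 1 :] = row
        values[i + 1 :, i] = row
    return DistanceMatrix(values=values, ids=tuple(library.ids), variant=variant)


def target_distances(
    u_target: DisplacementField, library: AtlasLibrary, variant: str = "rms"
) -> np.ndarray:
    """Length-n vector of distances from a target to every library entry."""
    _check_variant(variant)
    library.grid.require_match(u_target.grid)
    return np.array([field_distance(u_target, e.field, variant) for e in library])
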