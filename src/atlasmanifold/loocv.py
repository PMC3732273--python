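"""Leave-one-out optimization over (technique, d, k_D, k_d).

For each library entry the fold excludes the entry *and* its same-subject
sibling (the mirrored copy of the same hippocampus), learns the manifold on
the remainder, extends it with the held-out target's distance vector,
selects the k_d manifold-nearest atlases, fuses them with STAPLE and scores
the result with Dice's index against the held-out labels.  Averaging over
all folds fills one cell of the 4-D mean-Dice matrix; the argmax cell is
the optimized technique + parameters.

The BASE comparator performs the same fold, selection-by-distance and
fusion, but ranks atlases directly in the high-dimensional metric space
(no embedding).

The average-atlas reference is *not* rebuilt per fold: displacement fields
to the fixed reference are reused (recorded in the result metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DisconnectedGraphError
from .evaluate import dice
from .extend import extend, nearest_on_manifold
from .fusion import RaterStack, staple
from .manifold import TECHNIQUES, compute_embedding
from .metric import DistanceMatrix, distance_matrix
from .volume_io import AtlasLibrary

__all__ = ["ParamGrid", "GridResult", "fold_indices", "loocv_cell", "grid_search", "base_selection", "base_loocv"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamGrid:
    """Axes of the 4-D leave-one-out search."""

    techniques: Tuple[str, ...] = TECHNIQUES
    d_values: Tuple[int, ...] = tuple(range(1, 26, 2))
    k_D_values: Tuple[int, ...] = tuple(range(5, 26, 2))
    k_d_values: Tuple[int, ...] = tuple(range(1, 20, 2))

    def __post_init__(self):
        for name in ("techniques", "d_values", "k_D_values", "k_d_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
        for t in self.techniques:
            if t not in TECHNIQUES:
                raise ValueError(f"unknown technique {t!r}")
        for name in ("d_values", "k_D_values", "k_d_values"):
            if any(int(v) < 1 for v in getattr(self, name)):
                raise ValueError(f"{name} must be >= 1")
        object.__setattr__(self, "techniques", tuple(self.techniques))
        object.__setattr__(self, "d_values", tuple(int(v) for v in self.d_values))
        object.__setattr__(self, "k_D_values", tuple(int(v) for v in self.k_D_values))
        object.__setattr__(self, "k_d_values", tuple(int(v) for v in self.k_d_values))

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return (len(self.techniques), len(self.d_values), len(self.k_D_values), len(self.k_d_values))


@dataclass
class GridResult:
    """The 4-D mean-Dice matrix and the optimum it identifies."""

    grid: ParamGrid
    mean_dice: np.ndarray  # NaN marks a missing cell
    sd_dice: np.ndarray
    per_target_dice: Optional[np.ndarray]  # (..., n) when stored
    failed_folds: np.ndarray  # count of folds skipped per cell
    best: Tuple[str, int, int, int]
    metadata: Dict = field(default_factory=dict)

    def best_mean_dice(self) -> float:
        t, d, kD, kd = self.best
        return float(
            self.mean_dice[
                self.grid.techniques.index(t),
                self.grid.d_values.index(d),
                self.grid.k_D_values.index(kD),
                self.grid.k_d_values.index(kd),
            ]
        )

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for it, tech in enumerate(self.grid.techniques):
            for i_d, d in enumerate(self.grid.d_values):
                for ik, kD in enumerate(self.grid.k_D_values):
                    for il, kd in enumerate(self.grid.k_d_values):
                        rows.append(
                            {
                                "technique": tech,
                                "d": d,
                                "k_D": kD,
                                "k_d": kd,
                                "mean_dice": self.mean_dice[it, i_d, ik, il],
                                "sd_dice": self.sd_dice[it, i_d, ik, il],
                                "failed_folds": int(self.failed_folds[it, i_d, ik, il]),
                            }
                        )
        return pd.DataFrame(rows)


def fold_indices(library: AtlasLibrary, target_index: int) -> List[int]:
    """Indices kept in the fold for one target: drop it and its sibling(s).

    Entries sharing the target's ``subject_id`` (its mirrored copy) are
    excluded together with the target itself.
    """
    subj = library[target_index].subject_id
    keep = []
    for i, e in enumerate(library):
        if i == target_index:
            continue
        if subj is not None and e.subject_id == subj:
            continue
        keep.append(i)
    return keep


def _fuse_and_score(
    library: AtlasLibrary,
    keep: Sequence[int],
    selected_ids: Sequence[str],
    target_index: int,
    beta: float,
) -> float:
    id_to_idx = {library[i].id: i for i in keep}
    maps = [library[id_to_idx[a]].label_map for a in selected_ids]
    stack = RaterStack.from_label_maps(maps, tuple(selected_ids))
    result = staple(stack, beta=beta)
    return dice(result.fused, library[target_index].label_map)


def loocv_cell(
    library: AtlasLibrary,
    technique: str,
    d: int,
    k_D: int,
    k_d: int,
    beta: float = 0.2,
    variant: str = "rms",
    t: float = 1.0,
    reg: float = 1e-3,
    distances: Optional[DistanceMatrix] = None,
) -> Tuple[float, float, np.ndarray]:
    """Mean/SD/per-target Dice of one (technique, d, k_D, k_d) cell.

    Raises :class:`DisconnectedGraphError` if any fold's graph is
    disconnected (``grid_search`` catches this and marks the cell missing).
    """
    n = len(library)
    D = distances if distances is not None else distance_matrix(library, variant)
    scores = np.zeros(n)
    for ti in range(n):
        keep = fold_indices(library, ti)
        if len(keep) - 1 < k_D or k_d > len(keep):
            raise ValueError(f"fold size {len(keep)} too small for k_D={k_D}, k_d={k_d}")
        subD = D.submatrix(keep)
        emb = compute_embedding(technique, subD, d, k_D, t=t, reg=reg)
        t_emb = extend(emb, D.values[ti, keep], target_id=library[ti].id)
        sel = nearest_on_manifold(emb, t_emb, k_d)
        scores[ti] = _fuse_and_score(library, keep, sel, ti, beta)
    sd = float(scores.std(ddof=1)) if n > 1 else 0.0
    return float(scores.mean()), sd, scores


def grid_search(
    library: AtlasLibrary,
    grid: ParamGrid,
    beta: float = 0.2,
    variant: str = "rms",
    t: float = 1.0,
    reg: float = 1e-3,
    distances: Optional[DistanceMatrix] = None,
    store_per_target: bool = True,
    progress: bool = False,
) -> GridResult:
    """Fill the 4-D mean-Dice matrix and locate its maximum.

    Distance submatrices, graphs and embeddings are cached across cells
    within each fold; caching is semantically invisible (a cache-free rerun
    of any cell gives identical numbers).  Cells whose graph disconnects in
    any fold are marked missing (NaN) with the count of failed folds.
    Ties at the maximum resolve to the earliest cell in (technique order as
    listed, then smaller d, k_D, k_d).
    """
    n = len(library)
    D = distances if distances is not None else distance_matrix(library, variant)
    shape = grid.shape
    sums = np.zeros(shape)
    sumsq = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    failed = np.zeros(shape, dtype=int)
    per_target = np.full(shape + (n,), np.nan) if store_per_target else None

    for ti in range(n):
        if progress:
            log.info("fold %d/%d (target %s)", ti + 1, n, library[ti].id)
        keep = fold_indices(library, ti)
        subD = D.submatrix(keep)
        dists_t = D.values[ti, keep]
        for ik, k_D in enumerate(grid.k_D_values):
            if len(keep) - 1 < k_D:
                failed[:, :, ik, :] += 1
                continue
            try:
                for it, tech in enumerate(grid.techniques):
                    for i_d, d in enumerate(grid.d_values):
                        emb = compute_embedding(tech, subD, d, k_D, t=t, reg=reg)
                        t_emb = extend(emb, dists_t, target_id=library[ti].id)
                        for il, k_d in enumerate(grid.k_d_values):
                            if k_d > len(keep):
                                failed[it, i_d, ik, il] += 1
                                continue
                            sel = nearest_on_manifold(emb, t_emb, k_d)
                            score = _fuse_and_score(library, keep, sel, ti, beta)
                            sums[it, i_d, ik, il] += score
                            sumsq[it, i_d, ik, il] += score**2
                            counts[it, i_d, ik, il] += 1
                            if per_target is not None:
                                per_target[it, i_d, ik, il, ti] = score
            except DisconnectedGraphError:
                failed[:, :, ik, :] += 1
                continue

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where((failed == 0) & (counts > 0), sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            (failed == 0) & (counts > 1),
            (sumsq - sums**2 / np.maximum(counts, 1)) / np.maximum(counts - 1, 1),
            np.nan,
        )
    sd = np.sqrt(np.clip(var, 0.0, None))

    if np.all(np.isnan(mean)):
        raise DisconnectedGraphError(np.zeros(n, dtype=int), 2)

    best_idx = None
    best_val = -np.inf
    for it in range(shape[0]):
        for i_d in range(shape[1]):
            for ik in range(shape[2]):
                for il in range(shape[3]):
                    v = mean[it, i_d, ik, il]
                    if np.isfinite(v) and v > best_val:
                        best_val = v
                        best_idx = (it, i_d, ik, il)
    best = (
        grid.techniques[best_idx[0]],
        grid.d_values[best_idx[1]],
        grid.k_D_values[best_idx[2]],
        grid.k_d_values[best_idx[3]],
    )
    return GridResult(
        grid=grid,
        mean_dice=mean,
        sd_dice=sd,
        per_target_dice=per_target,
        failed_folds=failed,
        best=best,
        metadata={
            "beta": beta,
            "variant": variant,
            "t": t,
            "reg": reg,
            "n": n,
            "reference_rebuilt_per_fold": False,
        },
    )


def base_selection(D: DistanceMatrix, target_dists: np.ndarray, k_d: int) -> list:
    """k_d nearest atlases directly in the high-dimensional metric space."""
    target_dists = np.asarray(target_dists, dtype=np.float64)
    if target_dists.shape != (D.n,):
        raise ValueError(f"expected length-{D.n} distances, got {target_dists.shape}")
    if not 1 <= k_d <= D.n:
        raise ValueError(f"k_d must be in [1, {D.n}], got {k_d}")
    order = np.argsort(target_dists, kind="stable")[:k_d]
    return [D.ids[i] for i in order]


def base_loocv(
    library: AtlasLibrary,
    k_d: int,
    beta: float = 0.2,
    variant: str = "rms",
    distances: Optional[DistanceMatrix] = None,
) -> Tuple[float, float, np.ndarray]:
    """Leave-one-out mean Dice of the BASE (no-manifold) comparator.

    Shares the fold construction and the fusion code path with
    :func:`loocv_cell`; only the selection rule differs.
    """
    n = len(library)
    D = distances if distances is not None else distance_matrix(library, variant)
    scores = np.zeros(n)
    for ti in range(n):
        keep = fold_indices(library, ti)
        if k_d > len(keep):
            raise ValueError(f"k_d={k_d} exceeds fold size {len(keep)}")
        subD = D.submatrix(keep)
        sel = base_selection(subD, D.values[ti, keep], k_d)
        scores[ti] = _fuse_and_score(library, keep, sel, ti, beta)
    sd = float(scores.std(ddof=1)) if n > 1 else 0.0
    return float(scores.mean()), sd, scores
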