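"""STAPLE label fusion with mean-field MRF, restricted to non-consensus voxels.

STAPLE treats each propagated atlas segmentation as a "rater" with unknown
sensitivity p_r and specificity q_r and estimates, by expectation
maximization, both the rater parameters and the per-voxel probability W_x
that the true label is foreground.  Two refinements used here:

* Voxels where all raters agree (the consensus region) are fixed to their
  unanimous label; EM updates only the non-consensus voxels, which reduces
  the bias that large trivially-agreeing regions (e.g. background) would
  otherwise exert on W.  The rater parameters are still estimated over the
  whole volume, with consensus voxels entering the sums at their fixed 0/1
  weights.
* A Markov random field provides spatial consistency: each E-step adds a
  mean-field term  beta * sum_{y in N6(x)} (2 W_y - 1)  to the voxel's
  log-odds before normalization, using the previous iteration's weights
  (consensus neighbours contribute their fixed labels).

The algorithm is deterministic; the ``seed`` argument exists for interface
symmetry with the stochastic parts of the pipeline and is unused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .volume_io import AtlasLibrary, LabelMap, VoxelGrid

__all__ = [
    "CONSENSUS_BG",
    "CONSENSUS_FG",
    "NON_CONSENSUS",
    "RaterStack",
    "StapleResult",
    "consensus_split",
    "staple",
    "fuse_target",
    "majority_vote",
]

CONSENSUS_BG = 0
CONSENSUS_FG = 1
NON_CONSENSUS = 2

_CLAMP = 1e-6


@dataclass(frozen=True)
class RaterStack:
    """R binary decisions (one per selected atlas) on a shared grid."""

    grid: VoxelGrid
    decisions: np.ndarray  # (R, nx, ny, nz) uint8
    rater_ids: tuple

    def __post_init__(self):
        d = np.asarray(self.decisions)
        if d.ndim != 4 or d.shape[0] < 1:
            raise ValueError(f"decisions must be (R, nx, ny, nz) with R >= 1, got {d.shape}")
        if d.shape[1:] != self.grid.dims:
            raise ValueError(f"decision shape {d.shape[1:]} != grid dims {self.grid.dims}")
        if not np.isin(np.unique(d), (0, 1)).all():
            raise ValueError("rater decisions must be binary")
        object.__setattr__(self, "decisions", d.astype(np.uint8))
        object.__setattr__(self, "rater_ids", tuple(self.rater_ids))
        if len(self.rater_ids) != d.shape[0]:
            raise ValueError("rater_ids length does not match decisions")

    @classmethod
    def from_label_maps(cls, label_maps: Sequence[LabelMap], rater_ids: Sequence[str]) -> "RaterStack":
        grid = label_maps[0].grid
        for lm in label_maps[1:]:
            grid.require_match(lm.grid)
        return cls(grid=grid, decisions=np.stack([lm.values for lm in label_maps]), rater_ids=tuple(rater_ids))

    @property
    def n_raters(self) -> int:
        return self.decisions.shape[0]


@dataclass
class StapleResult:
    probability: np.ndarray  # per-voxel P(true = fg)
    fused: LabelMap
    sensitivity: np.ndarray  # p_r
    specificity: np.ndarray  # q_r
    rater_ids: tuple
    iterations: int
    converged: bool
    consensus: np.ndarray  # per-voxel {CONSENSUS_BG, CONSENSUS_FG, NON_CONSENSUS}
    log_likelihood: List[float] = field(default_factory=list)


def consensus_split(s: RaterStack) -> np.ndarray:
    """Classify voxels as consensus-foreground/-background or non-consensus."""
    votes = s.decisions.sum(axis=0)
    codes = np.full(s.grid.dims, NON_CONSENSUS, dtype=np.uint8)
    codes[votes == s.n_raters] = CONSENSUS_FG
    codes[votes == 0] = CONSENSUS_BG
    return codes


def _neighbour_field(W: np.ndarray) -> np.ndarray:
    """Sum of (2*W_y - 1) over 6-connected neighbours, zero outside the grid."""
    spins = 2.0 * W - 1.0
    out = np.zeros_like(W)
    for axis in range(3):
        lead = [slice(None)] * 3
        trail = [slice(None)] * 3
        lead[axis] = slice(1, None)
        trail[axis] = slice(None, -1)
        out[tuple(trail)] += spins[tuple(lead)]
        out[tuple(lead)] += spins[tuple(trail)]
    return out


def staple(
    s: RaterStack,
    beta: float = 0.2,
    prior: Optional[float] = None,
    init_p: float = 0.99999,
    init_q: float = 0.99999,
    tol: float = 1e-7,
    max_iter: int = 100,
    seed: Optional[int] = None,
) -> StapleResult:
    """Run consensus-restricted STAPLE with a mean-field MRF of strength ``beta``.

    ``prior`` is the foreground prevalence P(T_x = 1) used in the E-step;
    when None it defaults to the mean rater vote over the non-consensus
    region.  Convergence is declared when the mean absolute change of the
    stacked (p, q) vector falls below ``tol``.
    """
    del seed  # deterministic algorithm; kept for interface symmetry
    if beta < 0:
        raise ValueError(f"MRF strength beta must be >= 0, got {beta}")
    R = s.n_raters
    codes = consensus_split(s)
    nc = codes == NON_CONSENSUS
    rater_ids = s.rater_ids

    prob = np.zeros(s.grid.dims, dtype=np.float64)
    prob[codes == CONSENSUS_FG] = 1.0

    if not nc.any():
        p = np.full(R, 1.0 - _CLAMP)
        q = np.full(R, 1.0 - _CLAMP)
        fused = LabelMap(grid=s.grid, values=(prob >= 0.5).astype(np.uint8))
        return StapleResult(prob, fused, p, q, rater_ids, 0, True, codes)

    D = s.decisions[:, nc].astype(np.float64)  # (R, M)
    M = D.shape[1]
    if prior is None:
        prior = float(D.mean())
    prior = float(np.clip(prior, _CLAMP, 1.0 - _CLAMP))
    logit_prior = np.log(prior) - np.log1p(-prior)

    degenerate = (D.sum(axis=1) == 0) | (D.sum(axis=1) == M)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} rater(s) are constant over the non-consensus "
            "region; their performance estimates are clamped",
            RuntimeWarning,
        )

    # Fixed consensus contributions to the M-step sums: on consensus-fg all
    # raters voted 1 (W=1), on consensus-bg all voted 0 (W=0).
    n_cfg = float((codes == CONSENSUS_FG).sum())
    n_cbg = float((codes == CONSENSUS_BG).sum())

    W = np.full(M, prior)
    prob[nc] = W
    p = np.full(R, float(init_p))
    q = np.full(R, float(init_q))
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    q = np.clip(q, _CLAMP, 1.0 - _CLAMP)

    loglik: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p, log_1p = np.log(p), np.log1p(-p)
        log_q, log_1q = np.log(q), np.log1p(-q)
        if beta == 0:
            # observed-data log-likelihood at the current parameters
            la = np.log(prior) + D.T @ log_p + (1.0 - D).T @ log_1p
            lb = np.log1p(-prior) + D.T @ log_1q + (1.0 - D).T @ log_q
            mx = np.maximum(la, lb)
            ll = float(np.sum(mx + np.log(np.exp(la - mx) + np.exp(lb - mx))))
            ll += n_cfg * (np.log(prior) + float(log_p.sum()))
            ll += n_cbg * (np.log1p(-prior) + float(log_q.sum()))
            loglik.append(ll)

        # E-step over non-consensus voxels
        lo = logit_prior + D.T @ (log_p - log_1q) + (1.0 - D).T @ (log_1p - log_q)
        if beta > 0:
            lo = lo + beta * _neighbour_field(prob)[nc]
        W = 1.0 / (1.0 + np.exp(-lo))
        prob[nc] = W

        # M-step over all voxels (consensus weights fixed at 0/1)
        sum_W = n_cfg + W.sum()
        sum_1W = n_cbg + (1.0 - W).sum()
        p_new = (n_cfg + D @ W) / sum_W
        q_new = (n_cbg + (1.0 - D) @ (1.0 - W)) / sum_1W
        p_new = np.clip(p_new, _CLAMP, 1.0 - _CLAMP)
        q_new = np.clip(q_new, _CLAMP, 1.0 - _CLAMP)

        delta = float(np.mean(np.abs(np.concatenate([p_new - p, q_new - q]))))
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    fused = LabelMap(grid=s.grid, values=(prob >= 0.5).astype(np.uint8))
    return StapleResult(prob, fused, p, q, rater_ids, it, converged, codes, loglik)


def majority_vote(s: RaterStack) -> LabelMap:
    """Simple vote-fusion baseline: foreground where >= half the raters agree."""
    votes = s.decisions.sum(axis=0)
    return LabelMap(grid=s.grid, values=(votes * 2 >= s.n_raters).astype(np.uint8))


def fuse_target(e, t, library: AtlasLibrary, k_d: int, beta: float = 0.2, **staple_kwargs) -> StapleResult:
    """Select the k_d manifold-nearest atlases and fuse their labels with STAPLE."""
    from .extend import nearest_on_manifold

    ids = nearest_on_manifold(e, t, k_d)
    maps = [library[library.index_of(i)].label_map for i in ids]
    stack = RaterStack.from_label_maps(maps, ids)
    return staple(stack, beta=beta, **staple_kwargs)
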