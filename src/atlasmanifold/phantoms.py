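"""Synthetic atlas libraries with known low-dimensional latent structure.

Each phantom is an ellipsoid template warped by a displacement field that is
*linear* in a q-dimensional latent coordinate:

    u_i(x) = sum_m  theta_im * basis_m(x),      theta_i ~ U[-1, 1]^q

with q fixed, deterministic, smooth, boundary-windowed basis fields.  Because
the fields are linear in theta and the rms metric is Euclidean on fields,
the squared metric distance between phantoms i and j is exactly the
quadratic form (theta_i - theta_j)^T G (theta_i - theta_j), where G is the
basis Gram matrix (mean voxel-wise inner products).  Latent geometry
therefore maps isometrically (up to the fixed form G) into metric space,
which is what makes these phantoms a ground-truth oracle for the manifold
and out-of-sample modules.

Labels are obtained by nearest-neighbour pull-back of the template through
the latent-driven warp, so the truth stays binary without any interpolation
policy.  Optionally, an independent smooth noise field per phantom is added
to the *stored* displacement field only, emulating registration/measurement
error: the anatomy (label) still comes from the clean latent warp, but the
field the metric sees is corrupted.  With noise the exact quadratic-form
identity no longer holds for the stored fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import FoldingWarpError
from .fusion import RaterStack
from .volume_io import AtlasEntry, AtlasLibrary, DisplacementField, LabelMap, VoxelGrid

__all__ = [
    "PhantomSet",
    "generate_library",
    "make_target",
    "simulate_raters",
    "basis_gram",
    "latent_signal_rms",
]


@dataclass
class PhantomSet:
    """A synthetic atlas library plus the latent ground truth that built it."""

    latent: np.ndarray  # (n, q)
    library: AtlasLibrary
    reference: LabelMap  # unwarped template = the theta = 0 phantom
    basis: np.ndarray  # (q, nx, ny, nz, 3), mm per unit theta
    amplitude: float
    seed: int
    noise_rms: float = 0.0
    noise: Optional[np.ndarray] = None  # (n, nx, ny, nz, 3) when noise_rms > 0
    label_noise_rms: float = 0.0

    @property
    def grid(self) -> VoxelGrid:
        return self.reference.grid

    @property
    def q(self) -> int:
        return self.latent.shape[1]


def _normalized_coords(grid: VoxelGrid) -> Tuple[np.ndarray, ...]:
    axes = [np.linspace(0.0, 1.0, d) for d in grid.dims]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _template_values(grid: VoxelGrid) -> np.ndarray:
    """Ellipsoid occupying roughly the central third of the grid.

    Deliberately anisotropic so the mid-sagittal flip produces a genuinely
    different shape family.
    """
    s = _normalized_coords(grid)
    centre = (0.5, 0.52, 0.48)
    semi = (0.32, 0.24, 0.20)
    r2 = sum(((si - ci) / ai) ** 2 for si, ci, ai in zip(s, centre, semi))
    return (r2 <= 1.0).astype(np.uint8)


def _basis_fields(grid: VoxelGrid, q: int, amplitude: float) -> np.ndarray:
    """q deterministic smooth vector fields, zero on the grid boundary.

    Field m pushes along voxel axis (m mod 3) with a windowed cosine pattern
    whose modulation axis and frequency advance with m, keeping the family
    linearly independent.
    """
    s = _normalized_coords(grid)
    window = np.sin(np.pi * s[0]) * np.sin(np.pi * s[1]) * np.sin(np.pi * s[2])
    basis = np.zeros((q,) + grid.dims + (3,))
    for m in range(q):
        comp = m % 3
        mod_axis = (m + 1 + m // 3) % 3
        freq = 1 + m // 3
        pattern = np.cos(np.pi * freq * s[mod_axis])
        basis[m, ..., comp] = amplitude * window * pattern
    return basis


class _NoiseModel:
    """Random smooth fields spanning many more modes than the latent basis.

    Modes are windowed sinusoids up to frequency 4 in every axis/component,
    projected into the orthogonal complement of the latent basis so noise
    perturbs the measured field without moving the anatomical coordinates.
    Fields are drawn with iid standard-normal coefficients and a *global*
    normalization chosen so the expected rms vector magnitude equals the
    requested value — individual fields fluctuate in magnitude, as real
    registration error does.
    """

    def __init__(self, grid: VoxelGrid, orthogonal_to: Optional[np.ndarray] = None):
        s = _normalized_coords(grid)
        window = np.sin(np.pi * s[0]) * np.sin(np.pi * s[1]) * np.sin(np.pi * s[2])
        patterns = []
        for axis in range(3):
            for freq in (1, 2, 3, 4):
                patterns.append(window * np.cos(np.pi * freq * s[axis]))
                patterns.append(window * np.sin(np.pi * freq * s[axis]))
        modes = []
        for comp in range(3):
            for pat in patterns:
                m = np.zeros(grid.dims + (3,))
                m[..., comp] = pat
                modes.append(m)
        M = np.stack(modes).reshape(len(modes), -1)
        if orthogonal_to is not None:
            basis_flat = orthogonal_to.reshape(orthogonal_to.shape[0], -1)
            Q, _ = np.linalg.qr(basis_flat.T)
            M = M - (M @ Q) @ Q.T
        self._modes = M
        self._shape = grid.dims + (3,)
        # E[mean |field|^2] with iid N(0,1) coefficients = sum_k mean |mode_k|^2
        self._expected_rms = float(np.sqrt((M**2).sum() / grid.n_voxels))

    def sample(self, rng: np.random.Generator, rms: float) -> np.ndarray:
        g = rng.normal(size=self._modes.shape[0])
        field = (g @ self._modes) * (rms / self._expected_rms)
        return field.reshape(self._shape)


def _check_invertible(field: DisplacementField) -> None:
    """Reject warps whose approximate Jacobian determinant is non-positive."""
    spacing = field.grid.spacing
    grads = []
    for comp in range(3):
        g = np.gradient(field.vectors[..., comp], *spacing, edge_order=1)
        grads.append(g)
    dims = field.grid.dims
    J = np.zeros(dims + (3, 3))
    for a in range(3):
        for b in range(3):
            J[..., a, b] = (1.0 if a == b else 0.0) - grads[a][b]
    det = np.linalg.det(J)
    if det.min() <= 0:
        raise FoldingWarpError(
            f"displacement field self-folds (min Jacobian det = {det.min():.3g}); "
            "reduce the amplitude"
        )


def _warp_label(template: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Nearest-neighbour pull-back: label(x) = template(x - u(x))."""
    grid = field.grid
    idx = np.meshgrid(*[np.arange(d) for d in grid.dims], indexing="ij")
    out = np.zeros(grid.dims, dtype=np.uint8)
    src = [
        np.rint(idx[a] - field.vectors[..., a] / grid.spacing[a]).astype(int) for a in range(3)
    ]
    valid = np.ones(grid.dims, dtype=bool)
    for a in range(3):
        valid &= (src[a] >= 0) & (src[a] < grid.dims[a])
    out[valid] = template[src[0][valid], src[1][valid], src[2][valid]]
    return out


def generate_library(
    n: int,
    q: int = 3,
    grid_dims: Tuple[int, int, int] = (16, 16, 16),
    amplitude: float = 1.5,
    seed: int = 0,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_rms: float = 0.0,
    label_noise_rms: float = 0.0,
    with_flipped: bool = False,
) -> PhantomSet:
    """Generate n phantoms from a q-dimensional latent family.

    ``amplitude`` is the mm scale of each basis field per unit latent
    coordinate.  ``noise_rms`` adds an independent smooth per-phantom field
    of that rms magnitude (mm) to the stored displacement field only — the
    label is always generated from the latent warp, so noise plays the role
    of registration error in the metric, not of anatomical variation.
    ``label_noise_rms`` independently perturbs each stored *label* by an
    extra smooth warp of that rms magnitude, emulating annotation and
    propagation error in the segmentations; it is invisible to the metric.
    With ``with_flipped`` the library is doubled by mid-sagittally mirrored
    copies sharing the native entry's subject id.
    """
    if n < 4:
        raise ValueError("need n >= 4 phantoms")
    if q < 1:
        raise ValueError("latent dimension q must be >= 1")
    grid = VoxelGrid(dims=grid_dims, spacing=spacing, sagittal_axis=0)
    rng = np.random.default_rng(seed)
    template = _template_values(grid)
    if template.sum() == 0:
        raise ValueError(f"grid {grid_dims} too small to hold the template")
    basis = _basis_fields(grid, q, amplitude)
    latent = rng.uniform(-1.0, 1.0, size=(n, q))
    noise_model = _NoiseModel(grid, orthogonal_to=basis) if (noise_rms > 0 or label_noise_rms > 0) else None
    noise = None
    if noise_rms > 0:
        noise = np.stack([noise_model.sample(rng, noise_rms) for _ in range(n)])
    label_noise = None
    if label_noise_rms > 0:
        label_noise = np.stack([noise_model.sample(rng, label_noise_rms) for _ in range(n)])

    lib = AtlasLibrary()
    for i in range(n):
        clean = np.tensordot(latent[i], basis, axes=1)
        label_vectors = clean if label_noise is None else clean + label_noise[i]
        warp = DisplacementField(grid=grid, vectors=label_vectors)
        _check_invertible(warp)
        lm = LabelMap(grid=grid, values=_warp_label(template, warp))
        fld = (
            DisplacementField(grid=grid, vectors=clean)
            if noise is None
            else DisplacementField(grid=grid, vectors=clean + noise[i])
        )
        lib.add(
            AtlasEntry(
                id=f"phantom{i:03d}",
                label_map=lm,
                field=fld,
                laterality="native",
                subject_id=f"s{i:03d}",
            )
        )
    if with_flipped:
        lib = lib.with_flipped()
    return PhantomSet(
        latent=latent,
        library=lib,
        reference=LabelMap(grid=grid, values=template),
        basis=basis,
        amplitude=amplitude,
        seed=seed,
        noise_rms=noise_rms,
        noise=noise,
        label_noise_rms=label_noise_rms,
    )


def make_target(ps: PhantomSet, theta) -> Tuple[LabelMap, DisplacementField]:
    """Build a target (truth label, displacement field) at latent ``theta``.

    Constructed exactly like library entries (no noise term) and not added
    to the library.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape != (ps.q,):
        raise ValueError(f"theta must have length {ps.q}, got shape {theta.shape}")
    vectors = np.tensordot(theta, ps.basis, axes=1)
    fld = DisplacementField(grid=ps.grid, vectors=vectors)
    _check_invertible(fld)
    truth = LabelMap(grid=ps.grid, values=_warp_label(ps.reference.values, fld))
    return truth, fld


def simulate_raters(truth: LabelMap, p: float, q_spec: float, R: int, seed: int) -> RaterStack:
    """Simulate R independent raters with sensitivity p and specificity q_spec.

    Each rater keeps a true-foreground voxel with probability p and flips a
    true-background voxel with probability 1 - q_spec.
    """
    if not (0 < p <= 1 and 0 < q_spec <= 1):
        raise ValueError("p and q_spec must lie in (0, 1]")
    if R < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    fg = truth.values.astype(bool)
    decisions = np.zeros((R,) + truth.grid.dims, dtype=np.uint8)
    for r in range(R):
        u = rng.random(truth.grid.dims)
        d = np.where(fg, u < p, u >= q_spec)
        decisions[r] = d.astype(np.uint8)
    return RaterStack(grid=truth.grid, decisions=decisions, rater_ids=tuple(f"rater{r}" for r in range(R)))


def basis_gram(ps: PhantomSet) -> np.ndarray:
    """Gram matrix G_mk = mean_x <basis_m(x), basis_k(x)> of the basis fields.

    Under the rms metric, d(i, j)^2 = (theta_i - theta_j)^T G (theta_i -
    theta_j) exactly (noise-free phantoms).
    """
    q = ps.basis.shape[0]
    flat = ps.basis.reshape(q, -1)
    return (flat @ flat.T) / ps.grid.n_voxels


def latent_signal_rms(ps: PhantomSet) -> float:
    """rms displacement magnitude of the latent-driven fields across the library."""
    fields = np.stack(
        [np.tensordot(ps.latent[i], ps.basis, axes=1) for i in range(len(ps.latent))]
    )
    mags2 = np.einsum("...k,...k->...", fields, fields)
    return float(np.sqrt(mags2.mean()))
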