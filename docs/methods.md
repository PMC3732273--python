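# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind `atlasmanifold`, and what the tests do and do not
establish about behaviour on real imaging data.

## Image representation and metric

Each image is represented by the displacement field (mm, one 3-vector per
voxel) of the non-rigid transformation relating it to a common average
atlas. Registration itself is out of scope: fields are consumed, not
computed, and the package never resamples or interpolates intensities. The
direction convention of the fields (image→average or average→image) is not
enforced, only consistency across a library, because the metric — a
difference of fields — is invariant to a consistent choice.

Two metric variants are implemented over all grid voxels:

* `rms` (default): `sqrt(mean_x ‖u_a(x) − u_b(x)‖²)`. This equals the
  Euclidean distance between the flattened fields divided by `sqrt(N)`,
  which makes the LLE local Gram construction from distances *exact* and
  gives clean metric axioms. It is the variant all defaults assume.
* `mean_magnitude`: `mean_x ‖u_a(x) − u_b(x)‖`, retained as an option for
  mean-displacement readings of transformation-based similarity.

Distances are computed over the full grid, not a foreground mask, with `N`
the voxel count of the grid.

## Embeddings

All three techniques start from the same connected `k_D`-nearest-neighbour
graph (edge weight = metric distance). Neighbour ties break to the smaller
index; symmetrization is by union (each node keeps all of its own `k_D`
nearest neighbours), with a mutual option. A disconnected graph raises an
error instead of silently using the largest component, because a silently
restricted fold would corrupt the leave-one-out mean-Dice matrix; the grid
search records such cells as missing.

* **Isomap**: all-pairs Dijkstra geodesics (exact, no landmark
  approximation — libraries are of order 10²), classical MDS of the squared
  geodesics, coordinates `v_k √λ_k` from the top-`d` positive eigenpairs.
  If fewer than `d` positive eigenvalues exist the dimension is truncated
  with a warning.
* **LLE**: reconstruction weights per atlas from its own `k_D` nearest
  neighbours. The local Gram `C_jk = ½(d_ij² + d_ik² − d_jk²)` is built from
  distances alone (exact under the rms variant), regularized by
  `reg·trace(C)·I` with `reg = 1e-3` by default, and solved through its
  eigendecomposition — numerically stable when `C` is rank-deficient, as
  happens for points on a low-dimensional patch. A neighbour at exactly
  zero distance *is* the point and receives all the weight (this is the
  exact constrained minimizer). Embedding = bottom non-trivial eigenvectors
  of `(I−W)ᵀ(I−W)`; the constant eigenvector at eigenvalue 0 is discarded.
* **Laplacian Eigenmaps**: heat-kernel weights `exp(−d²/t)` on graph edges
  with bandwidth `t = 1` by default (a binary-weight option exists), then
  the generalized problem `L f = λ Deg f`. Eigenvectors are
  `Deg`-orthonormal; the trivial constant eigenvector (λ ≈ 0, unique on a
  connected graph) is discarded.

Determinism: every coordinate column's sign is fixed so its
largest-magnitude entry is positive, and all ties break by index, so
re-running on identical input is bit-stable and permutation of the library
permutes coordinates exactly.

## Out-of-sample extension

A target contributes only its distance vector to the training atlases. No
eigendecomposition is re-run and no displacement field is touched (for LLE
a `k_D×k_D` local weight system is solved by design).

* Isomap: target geodesics are approximated through the target's `k_D`
  nearest training points acting as gateways
  (`geo(t,j) = min_m dists_m + geo(m,j)`; a `gateways="all"` option uses
  every training point), then the kernel-MDS Nyström formula
  `y_k = (Σ_j v_jk (colmean_j(G²) − geo(t,j)²)) / (2√λ_k)`. For a training
  row this is exact to machine precision.
* LLE: reconstruction weights of the target from its `k_D` nearest training
  points (same Gram + regularization as training), coordinates = weighted
  combination of neighbour coordinates. Exact for on-manifold points.
* LEM: kernel row over the `k_D` nearest training points normalized by the
  target's own kernel degree, projected on the stored eigenvectors and
  divided by the kernel-form eigenvalues `1 − λ_k`. An all-zero kernel row
  (target too far at this bandwidth) raises rather than silently returning
  the origin.

**Exact-match rule.** A target at exactly zero metric distance from a
training atlas receives that atlas's coordinates directly, for every
technique. For Isomap the Nyström formula already has this property and
for LLE the zero-distance weight rule coincides with it, but for LEM it
cannot hold through the kernel row: a coincident target sees a self-kernel
term `exp(0)=1` that the training graph (which has no self-edges) never
had, and union symmetrization can give the training point graph neighbours
outside its own `k_D` list. Treating "distance exactly zero" as identity
is the physically meaningful resolution and keeps training-point
self-consistency exact for all three techniques.

The target is never inserted into the graph and the embedding is never
recomputed — the design scales with the atlas count, not with the number
of images segmented.

## STAPLE fusion with mean-field MRF

The selected atlases' label maps act as raters with unknown sensitivity
`p_r` and specificity `q_r`. Voxels where all raters agree are fixed to
the unanimous label; EM updates the per-voxel foreground probability `W_x`
only on the non-consensus region. The rater parameters, however, are
estimated over the *whole* volume with consensus voxels entering the
M-step sums at their fixed 0/1 weights: restricting the sums to the
non-consensus region would estimate rates *conditional on disagreement*,
which are systematically lower than the true global rates (with nine
raters at sensitivity 0.90 the conditional value is ≈ 0.84), while the
fixed-weight form recovers the simulation truth — the parameter-recovery
tests verify this to within 0.03 per run and 0.01 bias over 20 seeds.

Settings: prior = mean rater vote over the non-consensus region;
initialization `p_r = q_r = 0.99999`; convergence when the mean absolute
change of the stacked `(p, q)` vector drops below `1e-7`, at most 100
iterations; estimates clamped to `[1e-6, 1−1e-6]` (constant raters warn).
The MRF adds `β · Σ_{y∈N6(x)} (2W_y − 1)` to the E-step log-odds — one
mean-field sweep per EM iteration over the 6-connected neighbourhood,
consensus neighbours contributing their fixed labels, out-of-volume
neighbours contributing nothing. Default `β = 0.2`. Probability ≥ 0.5
(ties to foreground) yields the fused label. With `β = 0` the
observed-data log-likelihood is recorded each iteration and is
non-decreasing (asserted in tests). The algorithm has no stochastic step;
`seed` is accepted for interface symmetry only.

## Leave-one-out optimization

For each library entry the fold excludes the entry *and* every entry with
the same subject id (its mid-sagittally mirrored sibling), then runs
distances → embedding → extension → selection → fusion → Dice. The 4-D
mean-Dice matrix over `(technique, d, k_D, k_d)` is filled with caching
that is semantically invisible (verified cell-by-cell against uncached
reruns); its argmax, ties resolving to the earliest cell in listed
technique order then smaller `d`, `k_D`, `k_d`, is the optimized operating
point. The BASE comparator ranks atlases by raw metric distance and runs
through the identical fusion code path. The average-atlas reference is
**not** rebuilt per fold — rebuilding it would require groupwise
registration, which is out of scope — and this is recorded in the result
metadata; on synthetic data the reference is exact by construction, so the
approximation is only a caveat for real libraries.

The default grid (`d ∈ 1..25` odd, `k_D ∈ 5..25` odd, `k_d ∈ 1..19` odd)
mirrors the neighbourhoods around the hippocampal operating point; tests
and the acceptance script use smaller grids sized to their libraries.

## Synthetic phantoms: what they emulate

A phantom library is an ellipsoid template warped by fields **linear** in a
`q`-dimensional latent coordinate (`θ ~ U[−1,1]^q`, fixed windowed-cosine
basis fields, amplitude in mm per unit `θ`). Linearity + the rms metric
give the exact identity `d(i,j)² = (θ_i−θ_j)ᵀ G (θ_i−θ_j)` with `G` the
analytic basis Gram matrix — the ground-truth oracle behind the embedding
and extension tests. Labels are nearest-neighbour pull-backs of the
template through the warp (binary truth, no interpolation policy); warps
are rejected if the approximate Jacobian determinant of `x ↦ x − u(x)`
is anywhere non-positive.

Two independent error processes can be layered on top, both smooth random
fields drawn from a fixed mode family (windowed sinusoids to frequency 4)
projected orthogonal to the latent basis, with iid coefficients and a
global normalization so per-field magnitudes fluctuate as real error does:

* **field noise** (`noise_rms`) perturbs only the *stored* displacement
  field — registration/measurement error visible to the metric but not to
  the anatomy;
* **label noise** (`label_noise_rms`) perturbs only the *stored* label via
  an extra warp — annotation and propagation error invisible to the metric.

Rater simulation (`simulate_raters`) flips foreground voxels with
probability `1−p` and background voxels with probability `1−q`,
independently per rater, for the STAPLE recovery studies.

**Frozen study conditions.** The leave-one-out behaviour studies use 30
phantoms, `q = 3` latent modes, a 16³ grid at 1 mm, basis amplitude 2.5 mm
(pairwise Dice spanning roughly 0.6–0.95, the regime of hippocampal
multi-atlas work), field noise at 1.5× and label noise at 0.5× the latent
signal rms (≈ 0.40 mm). With clean labels and noise-free fields the single
nearest atlas is trivially optimal and fusing more can only dilute it;
with both error processes present the study reproduces the qualitative
behaviour expected of real libraries: Dice rises to an interior optimum in
`k_d` and declines as dissimilar atlases are added, accuracy flattens once
`d` reaches the planted latent dimension, and manifold selection matches
or beats BASE on average (the advantage is assessed as a mean over four
independently generated libraries because it is genuinely stochastic at
this library size). The STAPLE recovery study uses a 24³ template truth
(~790 foreground voxels) with `R = 9`, `p = 0.90`, `q = 0.95`.

What passing these tests does **not** show: phantoms have no intensity
model, no hippocampal shape realism, no disease-related morphometry, and
their latent family is flat (linear in `θ`) — so the studies validate the
machinery and its qualitative behaviour, not expected Dice levels on MRI.

## Known limitations

* The exact-match rule makes LEM extension discontinuous in the limit of a
  target approaching a training atlas (the kernel-row value it replaces
  differs at order `1/deg`); in practice targets coincide with atlases
  only in self-consistency checks.
* STAPLE is binary; multi-label fusion is out of scope, as are voting-rule
  and shape-averaging fusers.
* The per-fold average atlas is reused rather than rebuilt (see above).
* `mean_magnitude` distances make the LLE Gram construction approximate;
  the rms variant is recommended whenever LLE is used.
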