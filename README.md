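# atlasmanifold

Manifold-guided atlas selection for multi-atlas segmentation.

Multi-atlas segmentation labels a target image by propagating and fusing the
segmentations of the atlases that best match it. Which atlases to fuse is
the critical choice: this package selects them on a **low-dimensional
manifold** learned from the library's deformation geometry rather than in
the raw high-dimensional space. It was built for hippocampus segmentation
in T1 MRI, where each atlas is a manually delineated hippocampal label map,
but nothing in the code is specific to that structure.

## Method

Every image (atlas or target) is represented by the displacement field
`u : Ω → ℝ³` (mm) of the non-rigid transformation relating it to a common
average atlas `M`, so any two images can be compared without registering
them to each other:

```
d(A_i, A_j) = sqrt( (1/N) · Σ_x ‖u_i(x) − u_j(x)‖² )        (rms variant)
```

with `N` the number of voxels (a mean-magnitude variant is also provided).
The pipeline is then:

1. **Learn the manifold.** Build a connected `k_D`-nearest-neighbour graph
   on the `n×n` distance matrix and embed it in `d ≪ N` dimensions with one
   of three spectral techniques — Isomap (geodesic-preserving classical
   MDS), Locally Linear Embedding (local affine reconstruction weights) or
   Laplacian Eigenmaps (heat-kernel graph Laplacian, `L f = λ Deg f`).
2. **Extend with the target.** A new image needs only its distance vector
   to the training atlases (one registration to `M`); the Nyström
   out-of-sample extension places it on the precomputed manifold without
   re-solving any eigenproblem.
3. **Select and fuse.** The `k_d` atlases nearest to the target in embedding
   coordinates (L2) are fused with STAPLE: an EM algorithm that estimates
   each atlas's sensitivity `p_r` and specificity `q_r` together with the
   per-voxel probability of the true label, run only on non-consensus
   voxels and spatially regularized by a mean-field Markov random field of
   strength `β`.

`(technique, d, k_D, k_d)` are optimized by a leave-one-out experiment that
fills a 4-D matrix of mean Dice similarity indexes, with a `BASE`
comparator (nearest neighbours in the raw metric space) fused through the
identical STAPLE path. A synthetic-phantom module generates libraries from
a known low-dimensional latent family — fields linear in the latent
coordinate, so metric distances are an exact quadratic form in latent space
— with optional registration-error noise on the fields and annotation noise
on the labels; it makes every stage testable without imaging data.

## Worked example

```python
from atlasmanifold import (PipelineConfig, generate_library, make_target,
                           run_pipeline)

ps = generate_library(n=30, q=3, grid_dims=(16, 16, 16), amplitude=2.5, seed=0)
truth, field = make_target(ps, 0.3 * ps.latent[4] + 0.7 * ps.latent[11])

config = PipelineConfig(technique="lle", d=3, k_D=8, k_d=7, beta=0.2)
result, report = run_pipeline(config, ps.library, field, truth=truth)
print(report.selected_ids)
print(report.dice)
```

prints

```
['phantom011', 'phantom014', 'phantom015', 'phantom010', 'phantom021', 'phantom019', 'phantom002']
0.9772413793103448
```

— the seven atlases nearest to the target on the LLE manifold (the target
was synthesized 70 % of the way towards phantom 11, which duly ranks
first), and the Dice overlap between the STAPLE-fused label and the known
synthetic truth. `examples/` contains one short script per capability
(library simulation, embedding + selection, STAPLE fusion, the full
pipeline, and the leave-one-out grid search); each prints the quantities it
computes with a line on what they mean. A thin CLI mirrors the stages:

```bash
atlasmanifold simulate --n 30 --latent-dim 3 --grid 16 --out lib/
atlasmanifold distances --library lib/ --out D.tsv
atlasmanifold embed --distances D.tsv --technique lle --dim 3 --graph-k 8 --out emb.tsv
atlasmanifold run --library lib/ --target-field target.nii.gz --out fused.nii.gz
```

The library defaults (`PipelineConfig()`) are the optimized operating point
for hippocampal libraries: LLE with `d=11`, `k_D=23`, `k_d=7`, MRF strength
`β=0.2`, rms metric.

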