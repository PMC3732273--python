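"""STAPLE fusion: consensus handling, EM correctness, MRF behaviour."""

import numpy as np
import pytest

from atlasmanifold import (
    LabelMap,
    RaterStack,
    VoxelGrid,
    compute_embedding,
    consensus_split,
    dice,
    extend,
    fuse_target,
    majority_vote,
    simulate_raters,
    staple,
)
from atlasmanifold.fusion import CONSENSUS_BG, CONSENSUS_FG, NON_CONSENSUS


def _stack(grid, masks):
    return RaterStack(
        grid=grid,
        decisions=np.stack(masks).astype(np.uint8),
        rater_ids=tuple(f"r{i}" for i in range(len(masks))),
    )


class TestConsensusSplit:
    def test_identical_raters_full_consensus(self, rng):
        grid = VoxelGrid(dims=(6, 6, 6))
        mask = (rng.random(grid.dims) < 0.3).astype(np.uint8)
        codes = consensus_split(_stack(grid, [mask] * 4))
        assert (codes != NON_CONSENSUS).all()
        assert ((codes == CONSENSUS_FG) == mask.astype(bool)).all()

    def test_half_split_block(self):
        grid = VoxelGrid(dims=(8, 8, 8))
        left = np.zeros(grid.dims)
        left[:4] = 1
        right = np.zeros(grid.dims)
        right[4:] = 1
        codes = consensus_split(_stack(grid, [left, right]))
        assert (codes == NON_CONSENSUS).all()

    def test_counts_match_per_voxel_oracle(self, rng):
        grid = VoxelGrid(dims=(5, 5, 5))
        masks = [(rng.random(grid.dims) < 0.4) for _ in range(3)]
        codes = consensus_split(_stack(grid, masks))
        for idx in np.ndindex(grid.dims):
            votes = sum(int(m[idx]) for m in masks)
            expect = CONSENSUS_FG if votes == 3 else CONSENSUS_BG if votes == 0 else NON_CONSENSUS
            assert codes[idx] == expect


def _staple_oracle(decisions, beta=0.0, prior=None, init=0.99999, tol=1e-7, max_iter=100):
    """Per-voxel EM coded with explicit loops, independent of the package."""
    R = decisions.shape[0]
    dims = decisions.shape[1:]
    votes = decisions.sum(axis=0)
    codes = np.full(dims, 2, dtype=int)
    codes[votes == R] = 1
    codes[votes == 0] = 0
    nc = [idx for idx in np.ndindex(dims) if codes[idx] == 2]
    if prior is None:
        prior = float(np.mean([decisions[(r,) + idx] for idx in nc for r in range(R)]))
    W = {idx: prior for idx in nc}
    p = [init] * R
    q = [init] * R
    n_cfg = int((codes == 1).sum())
    n_cbg = int((codes == 0).sum())
    for _ in range(max_iter):
        newW = {}
        for idx in nc:
            a = prior
            b = 1.0 - prior
            for r in range(R):
                d = decisions[(r,) + idx]
                a *= p[r] if d else (1.0 - p[r])
                b *= (1.0 - q[r]) if d else q[r]
            newW[idx] = a / (a + b)
        W = newW
        p_new, q_new = [], []
        for r in range(R):
            num_p = n_cfg + sum(W[idx] * decisions[(r,) + idx] for idx in nc)
            den_p = n_cfg + sum(W.values())
            num_q = n_cbg + sum((1 - W[idx]) * (1 - decisions[(r,) + idx]) for idx in nc)
            den_q = n_cbg + sum(1 - w for w in W.values())
            p_new.append(min(max(num_p / den_p, 1e-6), 1 - 1e-6))
            q_new.append(min(max(num_q / den_q, 1e-6), 1 - 1e-6))
        delta = np.mean(np.abs(np.array(p_new + q_new) - np.array(p + q)))
        p, q = p_new, q_new
        if delta < tol:
            break
    prob = np.zeros(dims)
    prob[codes == 1] = 1.0
    for idx, w in W.items():
        prob[idx] = w
    return prob, np.array(p), np.array(q)


class TestStaple:
    def test_unanimous_raters_short_circuit(self, rng):
        grid = VoxelGrid(dims=(6, 6, 6))
        mask = (rng.random(grid.dims) < 0.3).astype(np.uint8)
        res = staple(_stack(grid, [mask] * 5))
        np.testing.assert_array_equal(res.fused.values, mask)
        assert (res.sensitivity >= 1 - 1e-5).all()
        assert (res.specificity >= 1 - 1e-5).all()
        assert res.iterations == 0

    def test_beta_zero_matches_independent_em_oracle(self):
        grid = VoxelGrid(dims=(2, 2, 1))
        r1 = np.array([[[1], [1]], [[0], [1]]])
        r2 = np.array([[[1], [0]], [[0], [1]]])
        r3 = np.array([[[1], [1]], [[0], [0]]])
        stack = _stack(grid, [r1, r2, r3])
        res = staple(stack, beta=0.0)
        prob, p, q = _staple_oracle(stack.decisions.astype(int))
        np.testing.assert_allclose(res.probability, prob, atol=1e-10)
        np.testing.assert_allclose(res.sensitivity, p, atol=1e-10)
        np.testing.assert_allclose(res.specificity, q, atol=1e-10)

    def test_beta_zero_matches_oracle_on_random_volume(self, rng):
        grid = VoxelGrid(dims=(4, 4, 3))
        truth = (rng.random(grid.dims) < 0.4)
        masks = [np.logical_xor(truth, rng.random(grid.dims) < 0.15) for _ in range(4)]
        stack = _stack(grid, masks)
        res = staple(stack, beta=0.0)
        prob, p, q = _staple_oracle(stack.decisions.astype(int))
        np.testing.assert_allclose(res.probability, prob, atol=1e-10)

    def test_parameter_recovery(self, phantoms24_truth):
        stack = simulate_raters(phantoms24_truth, 0.90, 0.95, 9, seed=7)
        res = staple(stack, beta=0.2)
        assert np.abs(res.sensitivity - 0.90).mean() < 0.03
        assert np.abs(res.specificity - 0.95).mean() < 0.03

    def test_staple_beats_majority_vote_with_heterogeneous_raters(self, phantoms24_truth):
        # STAPLE's advantage over voting is rater weighting: give it a mix of
        # reliable and poor raters
        good = simulate_raters(phantoms24_truth, 0.95, 0.99, 4, seed=3)
        bad = simulate_raters(phantoms24_truth, 0.55, 0.85, 5, seed=4)
        grid = phantoms24_truth.grid
        stack = RaterStack(
            grid=grid,
            decisions=np.concatenate([good.decisions, bad.decisions]),
            rater_ids=tuple(f"r{i}" for i in range(9)),
        )
        res = staple(stack, beta=0.2)
        mv = majority_vote(stack)
        assert dice(res.fused, phantoms24_truth) > dice(mv, phantoms24_truth)
        # estimated performance separates the two groups
        assert res.sensitivity[:4].min() > res.sensitivity[4:].max()

    def test_probability_bounds_and_monotone_loglik(self, phantoms24_truth):
        stack = simulate_raters(phantoms24_truth, 0.85, 0.93, 5, seed=2)
        res = staple(stack, beta=0.0)
        assert (res.probability >= 0.0).all() and (res.probability <= 1.0).all()
        ll = np.array(res.log_likelihood)
        assert len(ll) >= 2
        assert (np.diff(ll) >= -1e-8).all()

    def test_consensus_voxels_untouched(self, phantoms24_truth):
        stack = simulate_raters(phantoms24_truth, 0.9, 0.95, 5, seed=1)
        res = staple(stack, beta=0.2)
        codes = consensus_split(stack)
        assert (res.probability[codes == CONSENSUS_FG] == 1.0).all()
        assert (res.probability[codes == CONSENSUS_BG] == 0.0).all()
        np.testing.assert_array_equal(
            res.fused.values[codes == CONSENSUS_FG], 1
        )

    def test_mrf_resolves_isolated_disagreement(self):
        # one rater flips a single interior voxel of an agreed block; with
        # beta > 0 the neighbourhood pulls it back to foreground
        grid = VoxelGrid(dims=(7, 7, 7))
        block = np.zeros(grid.dims)
        block[1:6, 1:6, 1:6] = 1
        dissent = block.copy()
        dissent[3, 3, 3] = 0
        # two raters w/ random boundary noise keep the EM region non-trivial
        rng = np.random.default_rng(5)
        noisy1 = np.logical_xor(block, rng.random(grid.dims) < 0.02)
        noisy2 = np.logical_xor(block, rng.random(grid.dims) < 0.02)
        stack = _stack(grid, [block, dissent, noisy1, noisy2])
        res = staple(stack, beta=0.2)
        assert res.fused.values[3, 3, 3] == 1

    def test_sensitivity_specificity_bias_over_seeds(self, phantoms24_truth):
        bias_p, bias_q = [], []
        for seed in range(20):
            stack = simulate_raters(phantoms24_truth, 0.90, 0.95, 9, seed=seed)
            res = staple(stack, beta=0.2)
            bias_p.append(float((res.sensitivity - 0.90).mean()))
            bias_q.append(float((res.specificity - 0.95).mean()))
        assert abs(np.mean(bias_p)) < 0.01
        assert abs(np.mean(bias_q)) < 0.01

    def test_negative_beta_rejected(self, rng):
        grid = VoxelGrid(dims=(4, 4, 4))
        stack = _stack(grid, [(rng.random(grid.dims) < 0.5) for _ in range(2)])
        with pytest.raises(ValueError, match="beta"):
            staple(stack, beta=-0.1)


class TestFuseTarget:
    def test_k1_returns_nearest_atlas_labels(self, phantoms30, distances30):
        emb = compute_embedding("lle", distances30, 3, 8)
        t = extend(emb, distances30.values[6])
        res = fuse_target(emb, t, phantoms30.library, k_d=1, beta=0.2)
        np.testing.assert_array_equal(
            res.fused.values, phantoms30.library[6].label_map.values
        )

    def test_nearest_selection_beats_farthest(self, phantoms30, distances30):
        from atlasmanifold.extend import nearest_on_manifold
        from atlasmanifold.fusion import RaterStack

        emb = compute_embedding("lle", distances30, 3, 8)
        lib = phantoms30.library
        i = 4
        t = extend(emb, distances30.values[i])
        near = fuse_target(emb, t, lib, k_d=7, beta=0.2)
        all_ids = nearest_on_manifold(emb, t, len(lib))
        far_ids = all_ids[-7:]
        far_stack = RaterStack.from_label_maps(
            [lib[lib.index_of(a)].label_map for a in far_ids], tuple(far_ids)
        )
        far = staple(far_stack, beta=0.2)
        truth = lib[i].label_map
        assert dice(near.fused, truth) > dice(far.fused, truth)
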