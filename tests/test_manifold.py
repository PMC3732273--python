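"""Graph construction and the three embeddings: oracles and invariants."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from atlasmanifold import (
    DisconnectedGraphError,
    assert_connected,
    basis_gram,
    build_knn_graph,
    compute_embedding,
    embed_isomap,
    embed_lem,
    embed_lle,
)
from atlasmanifold.metric import DistanceMatrix


def _dm(values):
    n = len(values)
    return DistanceMatrix(np.asarray(values, dtype=float), ids=tuple(f"p{i}" for i in range(n)))


def _points_dm(points):
    return _dm(squareform(pdist(np.asarray(points, dtype=float))))


def _line_dm(n):
    return _points_dm(np.arange(n, dtype=float)[:, None])


class TestKnnGraph:
    def test_three_nodes_k2_complete(self):
        g = build_knn_graph(_line_dm(3), 2)
        assert g.mask.sum() == 6  # all off-diagonal pairs

    def test_line_k1_links_nearest(self):
        g = build_knn_graph(_line_dm(10), 1, symmetrization="union")
        for i in range(9):
            assert g.mask[i, i + 1]  # consecutive points adjacent
        assert not g.mask[0, 2]

    def test_brute_force_adjacency_oracle(self, rng):
        pts = rng.normal(size=(12, 4))
        D = _points_dm(pts)
        k = 3
        g = build_knn_graph(D, k)
        for i in range(12):
            order = sorted(range(12), key=lambda j: (D.values[i, j], j))
            nearest = [j for j in order if j != i][:k]
            # every own-nearest neighbour must be adjacent (union rule)
            for j in nearest:
                assert g.mask[i, j]
        np.testing.assert_array_equal(g.mask, g.mask.T)
        assert not g.mask.diagonal().any()

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            build_knn_graph(_line_dm(5), 5)

    def test_mutual_is_subset_of_union(self, rng):
        D = _points_dm(rng.normal(size=(15, 3)))
        union = build_knn_graph(D, 3, "union")
        mutual = build_knn_graph(D, 3, "mutual")
        assert (mutual.mask <= union.mask).all()


class TestConnectivity:
    def test_connected_single_component(self):
        g = build_knn_graph(_line_dm(8), 2)
        labels = assert_connected(g)
        assert len(set(labels)) == 1

    def test_two_far_clusters_disconnect(self):
        pts = np.concatenate([np.arange(5.0), 100.0 + np.arange(5.0)])[:, None]
        g = build_knn_graph(_points_dm(pts), 2)
        with pytest.raises(DisconnectedGraphError) as err:
            assert_connected(g)
        assert err.value.n_components == 2


class TestIsomap:
    def test_collinear_points_distances_preserved(self):
        D = _line_dm(10)
        emb = embed_isomap(build_knn_graph(D, 2), 1)
        got = squareform(pdist(emb.coords))
        np.testing.assert_allclose(got, D.values, atol=1e-9)

    def test_deterministic_rerun(self, distances12):
        a = embed_isomap(build_knn_graph(distances12, 5), 3)
        b = embed_isomap(build_knn_graph(distances12, 5), 3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_latent_recovery_procrustes(self):
        # the phantom latent coordinates are known to the generator: on a
        # densely sampled 2-D latent family the embedding must recover them
        # up to rotation/reflection/translation within 10% of latent scale
        from scipy.linalg import orthogonal_procrustes

        from atlasmanifold import distance_matrix, generate_library

        ps = generate_library(n=200, q=2, grid_dims=(12, 12, 12), amplitude=2.0, seed=7)
        D = distance_matrix(ps.library)
        emb = embed_isomap(build_knn_graph(D, 12), 2)
        G = basis_gram(ps)
        latent_iso = ps.latent @ np.linalg.cholesky(G)  # latent in metric units
        X = emb.coords - emb.coords.mean(0)
        Y = latent_iso - latent_iso.mean(0)
        R, _ = orthogonal_procrustes(X, Y)
        resid = np.linalg.norm(X @ R - Y) / np.linalg.norm(Y)
        assert resid < 0.1

    def test_d_truncated_with_warning(self):
        D = _line_dm(6)
        with pytest.warns(RuntimeWarning, match="truncating"):
            emb = embed_isomap(build_knn_graph(D, 2), 5)
        assert emb.d < 5


class TestLLE:
    def test_weight_rows_sum_to_one(self, distances12):
        emb = embed_lle(distances12, 5, 3)
        W = emb.cache["weights"]
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_affine_patch_reconstruction(self, rng):
        A = rng.normal(size=(2, 10))
        X = rng.normal(size=(20, 2)) @ A + rng.normal(size=10)
        emb = embed_lle(_points_dm(X), 5, 2, reg=1e-12)
        resid = np.linalg.norm(X - emb.cache["weights"] @ X, axis=1)
        assert resid.max() < 1e-8

    def test_local_gram_matches_vector_oracle(self, phantoms12, distances12):
        # rms distances are Euclidean on flattened fields, so the
        # distance-only Gram must equal the explicit inner-product Gram
        flat = phantoms12.library.fields_array().reshape(12, -1) / np.sqrt(
            phantoms12.grid.n_voxels
        )
        D = distances12.values
        i, k = 4, 5
        nbrs = build_knn_graph(distances12, k).knn_indices[i]
        d2 = D[i, nbrs] ** 2
        C = 0.5 * (d2[:, None] + d2[None, :] - D[np.ix_(nbrs, nbrs)] ** 2)
        diffs = flat[nbrs] - flat[i]
        np.testing.assert_allclose(C, diffs @ diffs.T, atol=1e-9)

    def test_trivial_eigenvalue_discarded(self, distances12):
        emb = embed_lle(distances12, 5, 3)
        assert abs(emb.cache["trivial_eigenvalue"]) < 1e-9
        assert (emb.eigenvalues >= -1e-12).all()


class TestLEM:
    def test_deg_orthonormal_eigenvectors(self, distances30):
        emb = embed_lem(build_knn_graph(distances30, 7), 4)
        Deg = np.diag(emb.cache["degrees"])
        gram = emb.coords.T @ Deg @ emb.coords
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_trivial_eigenpair_constant(self, distances30):
        emb = embed_lem(build_knn_graph(distances30, 7), 4)
        assert emb.cache["trivial_eigenvalue"] < 1e-9
        v0 = emb.cache["trivial_eigvec"]
        assert np.ptp(v0) < 1e-6

    def test_path_graph_monotone_first_coordinate(self):
        # dense-solver oracle: on a path of equally spaced points the first
        # non-trivial eigenvector is monotone along the path
        D = _line_dm(10)
        emb = embed_lem(build_knn_graph(D, 1), 1, t=10.0)
        first = emb.coords[:, 0]
        diffs = np.diff(first)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_invalid_bandwidth(self, distances12):
        with pytest.raises(ValueError, match="positive"):
            embed_lem(build_knn_graph(distances12, 5), 2, t=0.0)

    def test_binary_weighting_option(self, distances12):
        emb = embed_lem(build_knn_graph(distances12, 5), 2, weighting="binary")
        assert np.isfinite(emb.coords).all()


class TestCrossTechnique:
    @pytest.mark.parametrize("technique", ["isomap", "lle", "lem"])
    def test_permutation_equivariance(self, technique, rng):
        pts = rng.normal(size=(14, 5))
        D = _points_dm(pts)
        perm = rng.permutation(14)
        Dp = DistanceMatrix(
            D.values[np.ix_(perm, perm)], ids=tuple(D.ids[i] for i in perm)
        )
        a = compute_embedding(technique, D, 2, 5)
        b = compute_embedding(technique, Dp, 2, 5)
        np.testing.assert_allclose(b.coords, a.coords[perm], atol=1e-8)

    def test_techniques_differ_on_same_library(self, distances30):
        # each objective is different, so the embeddings must differ even
        # after optimal alignment
        from scipy.linalg import orthogonal_procrustes

        embs = {t: compute_embedding(t, distances30, 3, 8).coords for t in ("isomap", "lle", "lem")}
        names = list(embs)
        for i in range(3):
            for j in range(i + 1, 3):
                X = embs[names[i]] - embs[names[i]].mean(0)
                Y = embs[names[j]] - embs[names[j]].mean(0)
                X /= np.linalg.norm(X)
                Y /= np.linalg.norm(Y)
                R, _ = orthogonal_procrustes(X, Y)
                resid = np.linalg.norm(X @ R - Y)
                assert resid > 1e-6

    def test_neighbourhood_preservation_beats_random(self, phantoms30, distances30, rng):
        # mean recovery of latent k=7 neighbourhoods must beat a random embedding
        from scipy.spatial.distance import cdist

        lat = phantoms30.latent
        lat_nn = np.argsort(cdist(lat, lat), axis=1)[:, 1:8]
        def recovery(coords):
            emb_nn = np.argsort(cdist(coords, coords), axis=1)[:, 1:8]
            return np.mean(
                [len(set(lat_nn[i]) & set(emb_nn[i])) / 7.0 for i in range(len(lat))]
            )

        random_scores = [recovery(rng.normal(size=(30, 3))) for _ in range(20)]
        for technique in ("isomap", "lle", "lem"):
            coords = compute_embedding(technique, distances30, 3, 8).coords
            assert recovery(coords) > np.mean(random_scores)
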