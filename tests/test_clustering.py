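import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage

from dopavuln.clustering import (
    build_dendrogram,
    cluster_graph,
    cluster_kmeans,
    dendrogram_to_newick,
    embed_pca,
    normalize_log,
    select_hvgs,
    subcluster,
)

from conftest import make_adata


class TestNormalizeLog:
    def test_matches_hand_computation(self):
        counts = np.array([[1, 3], [10, 0], [2, 2]])
        adata = make_adata(counts)
        norm = normalize_log(adata, scale_target=1e4)
        dense = np.asarray(norm.X.todense())
        expected = np.log1p(counts / counts.sum(axis=1, keepdims=True) * 1e4)
        assert np.allclose(dense, expected)
        assert dense[1, 1] == 0.0  # zero count stays zero

    def test_depth_invariance(self):
        counts = np.array([[1, 3, 6]])
        doubled = 2 * counts
        n1 = normalize_log(make_adata(counts))
        n2 = normalize_log(make_adata(doubled))
        assert np.allclose(np.asarray(n1.X.todense()), np.asarray(n2.X.todense()))

    def test_zero_total_nucleus_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(make_adata(np.array([[0, 0], [1, 2]])))


class TestSelectHvgs:
    def test_planted_variable_genes_rank_first(self):
        rng = np.random.default_rng(0)
        n = 300
        flat = rng.poisson(5, size=(n, 30))
        bimodal = np.where(rng.random((n, 5)) < 0.5, 0, rng.poisson(40, size=(n, 5)))
        counts = np.hstack([flat, bimodal])
        adata = normalize_log(make_adata(counts))
        top = select_hvgs(adata, n=5)
        assert set(top) == {f"G{j}" for j in range(30, 35)}

    def test_constant_gene_never_selected(self):
        counts = np.ones((50, 10), dtype=int)
        counts[:, 1:] += np.random.default_rng(1).poisson(4, size=(50, 9))
        adata = normalize_log(make_adata(counts))
        # G0 is constant after depth normalization only if depths equal; use raw equal depths
        top = select_hvgs(adata, n=5)
        assert "G0" not in top

    def test_requesting_all_genes_returns_identity_set(self):
        counts = np.random.default_rng(2).poisson(3, size=(40, 12)) + 1
        adata = normalize_log(make_adata(counts))
        assert set(select_hvgs(adata, n=12)) == set(adata.var_names)

    def test_too_few_genes_warns_and_returns_all(self):
        counts = np.random.default_rng(3).poisson(3, size=(30, 6)) + 1
        adata = normalize_log(make_adata(counts))
        with pytest.warns(UserWarning, match="returning all"):
            out = select_hvgs(adata, n=50)
        assert len(out) == 6


class TestEmbedPca:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 4))
        adata = make_adata(np.zeros((40, 4), dtype=int))
        adata.X = sp.csr_matrix(X)
        emb = embed_pca(adata, [f"G{j}" for j in range(4)], d=4)
        Z = (X - X.mean(0)) / X.std(0)
        evals = np.sort(np.linalg.eigvalsh(Z.T @ Z))[::-1]
        comp_var = (emb**2).sum(axis=0)
        assert np.allclose(comp_var, evals, rtol=1e-8)

    def test_explained_variance_nonincreasing_and_sign_fixed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10)) * np.arange(1, 11)
        adata = make_adata(np.zeros((60, 10), dtype=int))
        adata.X = sp.csr_matrix(X)
        emb = embed_pca(adata, [f"G{j}" for j in range(10)], d=6)
        v = (emb**2).sum(axis=0)
        assert (np.diff(v) <= 1e-9).all()
        emb2 = embed_pca(adata, [f"G{j}" for j in range(10)], d=6)
        assert np.array_equal(emb, emb2)

    def test_rank_deficient_request_rejected(self):
        X = np.outer(np.arange(30.0), np.ones(5)) + np.arange(5)  # rank 1 after centering
        adata = make_adata(np.zeros((30, 5), dtype=int))
        adata.X = sp.csr_matrix(X)
        with pytest.raises(ValueError, match="rank"):
            embed_pca(adata, [f"G{j}" for j in range(5)], d=4)

    def test_low_rank_data_reconstructs(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(2, 8))
        coef = rng.normal(size=(50, 2))
        X = coef @ basis
        adata = make_adata(np.zeros((50, 8), dtype=int))
        adata.X = sp.csr_matrix(X)
        emb = embed_pca(adata, [f"G{j}" for j in range(8)], d=2)
        # two PCs capture all the variance of rank-2 data
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        assert (emb**2).sum() == pytest.approx((Z**2).sum(), rel=1e-8)


def two_blobs(n=150, sep=12.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d))
    b[:, 0] += sep
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n)
    perm = rng.permutation(2 * n)
    return X[perm], labels[perm]


class TestClusterGraph:
    def test_separated_blobs_recovered(self):
        X, truth = two_blobs()
        labels = cluster_graph(X, resolution=1.0, seed=0)
        assert len(np.unique(labels)) == 2
        # perfect agreement up to label swap
        tab = pd.crosstab(labels, truth)
        assert tab.max(axis=1).sum() == len(truth)

    def test_low_resolution_limit_single_cluster(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        labels = cluster_graph(X, resolution=1e-3, seed=0)
        assert len(np.unique(labels)) == 1

    def test_seeded_reproducibility(self):
        X, _ = two_blobs(seed=2)
        l1 = cluster_graph(X, resolution=1.0, seed=5)
        l2 = cluster_graph(X, resolution=1.0, seed=5)
        assert np.array_equal(l1, l2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_graph(np.zeros((5, 2)), resolution=1.0, k_neighbors=20)


class TestClusterKmeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        labels, cent = cluster_kmeans(X, k=1, seed=0)
        assert np.allclose(cent[0], X.mean(axis=0))
        assert (labels == 0).all()

    def test_k_equals_n_zero_within_ss(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 2))
        labels, cent = cluster_kmeans(X, k=9, seed=0)
        assert len(np.unique(labels)) == 9
        wss = sum(((X[labels == j] - cent[j]) ** 2).sum() for j in range(9))
        assert wss == pytest.approx(0.0, abs=1e-12)

    def test_blobs_match_brute_force_partition(self):
        # 10 points, 2 clear blobs: optimal 2-partition found by enumeration
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.3, size=(5, 2)), rng.normal(8, 0.3, size=(5, 2))])
        labels, cent = cluster_kmeans(X, k=2, seed=0)
        wss = sum(((X[labels == j] - cent[j]) ** 2).sum() for j in range(2))
        best = np.inf
        for assign in itertools.product([0, 1], repeat=10):
            assign = np.asarray(assign)
            if assign.min() == assign.max():
                continue
            s = 0.0
            for j in (0, 1):
                pts = X[assign == j]
                s += ((pts - pts.mean(axis=0)) ** 2).sum()
            best = min(best, s)
        assert wss == pytest.approx(best, rel=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_kmeans(np.zeros((3, 2)), k=5)


class TestDendrogram:
    def test_two_singletons_merge_at_euclidean_distance(self):
        cent = np.array([[0.0, 0.0], [3.0, 4.0]])
        Z = build_dendrogram(cent)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_nearest_pair_merges_first_and_heights_monotone(self):
        cent = np.array([[0.0], [1.0], [10.0], [10.5]])
        Z = build_dendrogram(cent)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {2, 3}  # the 0.5-apart pair merges before the 1.0 pair

    def test_duplicate_centroids_merge_at_zero(self):
        cent = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        Z = build_dendrogram(cent)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_newick_has_all_leaves(self):
        cent = np.random.default_rng(10).normal(size=(6, 3))
        nwk = dendrogram_to_newick(build_dendrogram(cent))
        assert nwk.endswith(";")
        for i in range(6):
            assert f"{i}:" in nwk


class TestSubcluster:
    def test_refines_parent_partition(self):
        X, truth = two_blobs(n=120, seed=3)
        labels = cluster_graph(X, resolution=1.0, seed=0)
        sub = subcluster(X, labels, resolution=0.5, seed=0)
        parents = sub.str.split(".").str[0].astype(int).to_numpy()
        assert np.array_equal(parents, labels)
        # every nucleus gets exactly one subcluster label
        assert sub.notna().all()
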