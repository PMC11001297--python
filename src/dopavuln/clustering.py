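"""Normalization, embedding and the clustering stack.

Depth-scaled log1p normalization stands in for regularized-NB variance
stabilization: every downstream statistic in this package (rank tests,
module scores, composition counts) depends only on per-nucleus relative
expression, not on the exact variance-stabilization flavor.

Clustering levels:

* graph clusters — shared-nearest-neighbor (SNN) graph, Jaccard edge
  weights pruned at 1/15, Louvain modularity with a resolution parameter;
* k-means (MacQueen online updates) on the PC embedding, whose centroids
  feed a Ward (ward.D2, Euclidean) dendrogram — the hierarchy on which
  territory/neighborhood-style groupings are read off;
* subclusters — Louvain at resolution 0.5 within each k-means cluster;
  these are the units of the cell-loss statistic.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "normalize_log",
    "select_hvgs",
    "embed_pca",
    "snn_graph",
    "cluster_graph",
    "cluster_kmeans",
    "build_dendrogram",
    "dendrogram_to_newick",
    "subcluster",
    "default_k",
    "ClusterModel",
]

SNN_PRUNE = 1.0 / 15.0


def normalize_log(adata: AnnData, scale_target: float = 1e4) -> AnnData:
    """Per-nucleus depth scaling to ``scale_target`` followed by log1p.

    x -> log1p(count / nucleus_total * scale_target).  Raises on zero-total
    nuclei (they should have been removed by QC).
    """
    counts = sp.csr_matrix(adata.layers.get("counts", adata.X), dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(f"{int((totals == 0).sum())} nuclei have zero total counts")
    scaled = sp.diags(scale_target / totals) @ counts
    scaled.data = np.log1p(scaled.data)
    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(adata.layers.get("counts", adata.X))
    out.X = scaled.tocsr()
    out.uns["normalization"] = {"method": "lognorm", "scale_target": scale_target}
    return out


def select_hvgs(adata_norm: AnnData, n: int = 1000) -> list[str]:
    """Top-``n`` genes by standardized dispersion (dispersion-in-mean-bins
    z-score, computed on the log-normalized matrix).  Deterministic."""
    X = sp.csr_matrix(adata_norm.X)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "dispersion": dispersion}, index=adata_norm.var_names)
    # ~100 genes per mean-expression bin; small panels fall back to one bin
    n_bins = min(20, max(1, len(df) // 100))
    df["bin"] = pd.cut(df["mean"].rank(method="first"), bins=n_bins, labels=False)
    grouped = df.groupby("bin", observed=True)["dispersion"]
    mu_b = grouped.transform("mean")
    sd_b = grouped.transform("std").replace(0.0, np.nan)
    df["dispersion_norm"] = ((df["dispersion"] - mu_b) / sd_b).fillna(0.0)
    if len(df) < n:
        warnings.warn(f"only {len(df)} genes available; returning all", stacklevel=2)
        n = len(df)
    order = df.sort_values(
        ["dispersion_norm"], ascending=False, kind="mergesort"
    ).index.tolist()
    return order[:n]


def embed_pca(adata_norm: AnnData, hvgs: list[str], d: int = 30) -> np.ndarray:
    """PCA of the z-scored HVG submatrix; columns ordered by decreasing
    explained variance, sign fixed so each component's largest-magnitude
    loading is positive."""
    if d > len(hvgs):
        raise ValueError(f"d={d} exceeds number of HVGs ({len(hvgs)})")
    sub = adata_norm[:, hvgs].X
    dense = np.asarray(sub.todense() if sp.issparse(sub) else sub, dtype=np.float64)
    dense -= dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    dense /= sd
    # SVD route: deterministic, gives loadings for the sign convention
    U, S, Vt = np.linalg.svd(dense, full_matrices=False)
    tol = max(dense.shape) * np.finfo(float).eps * (S[0] if len(S) else 0.0)
    rank = int((S > tol).sum())
    if d > rank:
        raise ValueError(f"d={d} exceeds data rank ({rank})")
    signs = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    emb = U[:, :d] * S[:d] * signs[:d]
    return emb


def snn_graph(
    embedding: np.ndarray, k_neighbors: int = 20, prune: float = SNN_PRUNE
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets
    (self-inclusive), edges below ``prune`` removed."""
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} nuclei, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    adj = adj.maximum(sp.eye(n, format="csr"))  # neighbor sets include self
    k = np.asarray(adj.sum(axis=1)).ravel()
    inter = (adj @ adj.T).tocoo()
    union = k[inter.row] + k[inter.col] - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    return sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))


def _louvain(graph: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(graph.maximum(graph.T), k=1).tocoo()
    g = igraph.Graph(
        n=graph.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel densely by decreasing cluster size (stable across runs)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.asarray([remap[l] for l in labels])


def cluster_graph(
    embedding: np.ndarray,
    resolution: float = 1.0,
    k_neighbors: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """SNN + Louvain community labels (dense, 0..m-1, size-ordered)."""
    graph = snn_graph(embedding, k_neighbors=k_neighbors)
    return _louvain(graph, resolution, seed)


def cluster_kmeans(
    embedding: np.ndarray,
    k: int,
    seed: int = 0,
    max_passes: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """MacQueen online k-means.

    Centroids initialize from k distinct data points; each pass visits the
    points in order, moving a point to its nearest centroid and updating the
    running means of the donor and recipient clusters immediately.  Stops at
    a pass with no moves, or ``max_passes``.  If a distinct-point
    initialization is impossible (fewer unique points than k) the surplus
    centroids are reseeded on random points (documented policy: reseed).
    """
    n = embedding.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    rng = np.random.default_rng(seed)
    uniq, first_idx = np.unique(embedding, axis=0, return_index=True)
    if len(uniq) >= k:
        chosen = rng.choice(first_idx, size=k, replace=False)
    else:  # reseed policy for duplicate-heavy data
        chosen = np.concatenate(
            [first_idx, rng.choice(n, size=k - len(uniq), replace=False)]
        )
    centroids = embedding[chosen].astype(np.float64).copy()
    labels = cdist(embedding, centroids).argmin(axis=1)
    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    for j in np.flatnonzero(sizes == 0):  # reseed empty clusters
        p = int(rng.integers(n))
        centroids[j] = embedding[p]
        labels[p] = j
        sizes = np.bincount(labels, minlength=k).astype(np.float64)
    for j in range(k):
        centroids[j] = embedding[labels == j].mean(axis=0)
    for _ in range(max_passes):
        moved = 0
        for i in range(n):
            d = ((centroids - embedding[i]) ** 2).sum(axis=1)
            new = int(d.argmin())
            old = int(labels[i])
            if new != old and sizes[old] > 1:
                centroids[old] = (centroids[old] * sizes[old] - embedding[i]) / (sizes[old] - 1)
                centroids[new] = (centroids[new] * sizes[new] + embedding[i]) / (sizes[new] + 1)
                sizes[old] -= 1
                sizes[new] += 1
                labels[i] = new
                moved += 1
        if moved == 0:
            break
    return labels, centroids


def build_dendrogram(centroids: np.ndarray) -> np.ndarray:
    """Ward (ward.D2) agglomeration on Euclidean centroid distances.

    Returns a scipy linkage matrix with ``len(centroids)`` leaves; duplicate
    centroids merge at height 0.
    """
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroids")
    return linkage(centroids, method="ward", metric="euclidean")


def dendrogram_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    tree = to_tree(Z)
    n = tree.count
    labels = labels or [str(i) for i in range(n)]

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def subcluster(
    embedding: np.ndarray,
    labels: np.ndarray,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Louvain within each cluster; labels like ``'3.1'`` refine ``3``.

    Clusters too small for a neighbor graph become a single subcluster.
    Singleton subclusters are retained.
    """
    out = pd.Series(index=np.arange(len(labels)), dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) <= 3:
            out.iloc[idx] = f"{c}.0"
            continue
        kn = min(k_neighbors, len(idx) - 1)
        sub = _louvain(snn_graph(embedding[idx], k_neighbors=kn), resolution, seed)
        out.iloc[idx] = [f"{c}.{s}" for s in sub]
    return out


def default_k(n_nuclei: int) -> int:
    """Default k-means k: ceil(n/500), floored at 8."""
    return max(8, int(np.ceil(n_nuclei / 500)))


@dataclass
class ClusterModel:
    """The full clustering state consumed by the loss statistic."""

    hvgs: list[str]
    embedding: np.ndarray
    graph_labels: np.ndarray | None
    kmeans_labels: np.ndarray
    centroids: np.ndarray
    linkage: np.ndarray
    subcluster_labels: pd.Series
    params: dict = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        adata_norm: AnnData,
        n_hvgs: int = 1000,
        d: int = 30,
        k: int | None = None,
        graph_resolution: float | None = None,
        subcluster_resolution: float = 0.5,
        k_neighbors: int = 20,
        seed: int = 0,
    ) -> "ClusterModel":
        hvgs = select_hvgs(adata_norm, n=n_hvgs)
        d_eff = min(d, len(hvgs))
        emb = embed_pca(adata_norm, hvgs, d=d_eff)
        k = k if k is not None else default_k(adata_norm.n_obs)
        km_labels, centroids = cluster_kmeans(emb, k=k, seed=seed)
        Z = build_dendrogram(centroids)
        g_labels = (
            cluster_graph(emb, resolution=graph_resolution, k_neighbors=k_neighbors, seed=seed)
            if graph_resolution is not None
            else None
        )
        sub = subcluster(
            emb, km_labels, resolution=subcluster_resolution, k_neighbors=k_neighbors, seed=seed
        )
        sub.index = adata_norm.obs_names
        return cls(
            hvgs=hvgs,
            embedding=emb,
            graph_labels=g_labels,
            kmeans_labels=km_labels,
            centroids=centroids,
            linkage=Z,
            subcluster_labels=sub,
            params={
                "n_hvgs": n_hvgs,
                "d": d_eff,
                "k": k,
                "graph_resolution": graph_resolution,
                "subcluster_resolution": subcluster_resolution,
                "k_neighbors": k_neighbors,
                "seed": seed,
            },
        )

    def labels_frame(self, obs_names) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.kmeans_labels.astype(int),
                "subcluster": self.subcluster_labels.to_numpy(),
            },
            index=obs_names,
        )
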