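"""Clustering-quality evaluation via average silhouette width in PC space.

The silhouette of droplet *i* is s(i) = (b(i) - a(i)) / max(a(i), b(i)),
with a(i) the mean distance to other members of its cluster and b(i) the
smallest mean distance to another cluster; members of singleton clusters get
s(i) = 0 by the standard convention.  Averaged over droplets it scores a
partition in [-1, 1] and lets filtered and unfiltered pipelines be compared
on identical downstream parameters.

Embeddings follow standard single-cell practice (library-size normalisation,
log1p, top variable genes, per-gene standardisation, PCA); silhouettes are
computed in PC space with Euclidean distance, never in tSNE space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .types import CountMatrix

__all__ = [
    "Embedding",
    "ClusterAssignment",
    "normalize_and_embed",
    "cluster_cells",
    "average_silhouette",
    "compare_pipelines",
]


@dataclass
class Embedding:
    barcodes: np.ndarray
    coordinates: np.ndarray  # droplets x components
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterAssignment:
    barcodes: np.ndarray
    cluster_id: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        if len(self.cluster_id) != len(self.barcodes):
            raise ValueError("one cluster ID per barcode required")
        ids = np.unique(self.cluster_id)
        if not np.array_equal(ids, np.arange(len(ids))):
            # re-map to contiguous IDs starting at 0
            remap = {c: i for i, c in enumerate(ids)}
            self.cluster_id = np.array([remap[c] for c in self.cluster_id])

    @property
    def k(self) -> int:
        return int(len(np.unique(self.cluster_id)))


def normalize_and_embed(
    matrix: CountMatrix,
    n_top_genes: int = 1000,
    n_components: int = 10,
    target_sum: float = 1e4,
) -> Embedding:
    """Standard normalisation + PCA embedding of a count matrix.

    Library-size normalisation to ``target_sum``, log(1+x), top variable
    genes by dispersion, per-gene standardisation, PCA.  Deterministic for a
    fixed input.  Droplets with zero counts cannot be normalised and must be
    filtered beforehand.
    """
    import scanpy as sc

    numi = matrix.umi_per_droplet()
    if np.any(numi == 0):
        raise ValueError(
            f"{int((numi == 0).sum())} droplet(s) have zero counts; filter them before embedding"
        )
    if matrix.n_droplets <= n_components:
        raise ValueError("need more droplets than PCA components")
    adata = matrix.to_anndata()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    if n_top_genes < matrix.n_genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(adata, n_top_genes=n_top_genes, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata)
    n_comps = min(n_components, adata.n_vars - 1, adata.n_obs - 1)
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=0)
    return Embedding(
        barcodes=matrix.barcodes.copy(),
        coordinates=np.asarray(adata.obsm["X_pca"], dtype=float),
        variance_explained=np.asarray(adata.uns["pca"]["variance_ratio"], dtype=float),
    )


def cluster_cells(
    embedding: Embedding, method: str = "kmeans", k: int = 8, seed: int = 0,
    **params,
) -> ClusterAssignment:
    """Cluster droplets in embedding space (k-means default, Leiden optional)."""
    n = len(embedding.barcodes)
    if method == "kmeans":
        if not 2 <= k <= n:
            raise ValueError(f"k={k} invalid for {n} droplets (need 2 <= k <= n)")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10, **params)
        labels = km.fit_predict(embedding.coordinates)
    elif method == "leiden":
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(X=embedding.coordinates.astype(np.float32))
        adata.obsm["X_pca"] = embedding.coordinates
        sc.pp.neighbors(adata, use_rep="X_pca", random_state=seed)
        sc.tl.leiden(adata, random_state=seed, flavor="igraph", n_iterations=2,
                     directed=False, **params)
        labels = adata.obs["leiden"].astype(int).to_numpy()
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterAssignment(embedding.barcodes.copy(), labels)


def average_silhouette(embedding: Embedding, clusters: ClusterAssignment) -> float:
    """Average silhouette width of a partition, Euclidean distance in PC space."""
    if clusters.k < 2:
        raise ValueError("silhouette is undefined for fewer than 2 clusters")
    if not np.array_equal(embedding.barcodes, clusters.barcodes):
        raise ValueError("embedding and cluster assignment barcodes do not align")
    return float(np.mean(silhouette_samples(embedding.coordinates, clusters.cluster_id)))


def silhouette_of_partition(
    embedding: Embedding,
    class_of: "pd.Series | dict",
    assign_missing: str = "nearest_centroid",
) -> float:
    """Average silhouette of a known (ground-truth) partition.

    ``class_of`` maps barcodes to class labels; droplets without a class
    (e.g. empty droplets, which belong to no cell type) are absorbed into the
    partition the way a clustering would absorb them: assigned to the class
    with the nearest centroid in embedding space (``assign_missing`` =
    ``"nearest_centroid"``) or dropped (``"drop"``).  This measures how well
    the embedded data separates the true classes — junk droplets forced into
    the partition degrade it.
    """
    mapping = dict(class_of) if not isinstance(class_of, dict) else class_of
    labels = np.array([mapping.get(b) for b in embedding.barcodes], dtype=object)
    known = np.array([l is not None and l == l for l in labels])  # not None/NaN
    classes = sorted({l for l in labels[known]})
    if len(classes) < 2:
        raise ValueError("partition silhouette needs at least 2 known classes")
    if not np.all(known):
        if assign_missing == "drop":
            coords = embedding.coordinates[known]
            emb = Embedding(embedding.barcodes[known], coords, embedding.variance_explained)
            ids = np.array([classes.index(l) for l in labels[known]])
            return average_silhouette(emb, ClusterAssignment(emb.barcodes, ids))
        if assign_missing != "nearest_centroid":
            raise ValueError(f"unknown assign_missing {assign_missing!r}")
        centroids = np.stack([
            embedding.coordinates[known & (labels == c)].mean(axis=0) for c in classes
        ])
        dist = np.linalg.norm(
            embedding.coordinates[~known][:, None, :] - centroids[None, :, :], axis=2
        )
        labels[~known] = np.asarray(classes, dtype=object)[np.argmin(dist, axis=1)]
    ids = np.array([classes.index(l) for l in labels])
    return average_silhouette(embedding, ClusterAssignment(embedding.barcodes.copy(), ids))


def compare_pipelines(
    matrix: CountMatrix,
    filter_variants: Sequence[tuple[str, Callable[[CountMatrix], Sequence[str]] | None]],
    n_top_genes: int = 1000,
    n_components: int = 10,
    k: int = 8,
    seed: int = 0,
    min_droplets: int = 50,
) -> pd.DataFrame:
    """Side-by-side clustering quality of several filter chains.

    Each variant is ``(name, selector)`` where ``selector(matrix)`` returns
    the barcodes to keep (``None`` keeps everything).  Every variant is
    embedded and clustered with identical downstream parameters; variants
    leaving fewer than ``min_droplets`` droplets are skipped with a warning.
    """
    rows = []
    for name, selector in filter_variants:
        kept = list(matrix.barcodes) if selector is None else list(selector(matrix))
        if len(kept) < min_droplets:
            warnings.warn(f"variant {name!r} leaves {len(kept)} droplets; skipped", stacklevel=2)
            continue
        sub = matrix.subset_droplets(kept)
        embedding = normalize_and_embed(sub, n_top_genes=n_top_genes, n_components=n_components)
        clusters = cluster_cells(embedding, k=k, seed=seed)
        rows.append(
            {
                "variant": name,
                "n_cells": len(kept),
                "k": clusters.k,
                "average_silhouette": average_silhouette(embedding, clusters),
            }
        )
    return pd.DataFrame(rows, columns=["variant", "n_cells", "k", "average_silhouette"])
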