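"""Cell subpopulation assignment and PCA embeddings.

Cells are clustered hierarchically on the highly variable genes using
1 - Pearson correlation distance and average linkage (the same correlation
geometry as the co-expression network).  If the number of groups K is not
given it is chosen in 2..max_clusters by maximum mean silhouette on the
correlation distance.  Group ids are ordered by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import EstimationError, ValidationError
from .normalize import NormalizedMatrix

__all__ = ["SubgroupAssignment", "Embedding", "pca_embed", "cluster_cells"]


@dataclass
class SubgroupAssignment:
    labels: np.ndarray  # per-cell group id, 1..K, ordered by decreasing size
    K: int
    linkage_tree: np.ndarray  # scipy linkage matrix (merge sequence + heights)
    distance: str = "correlation"
    linkage: str = "average"


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x n_components
    explained_variance_fraction: np.ndarray


def pca_embed(
    nm: NormalizedMatrix, gene_subset: np.ndarray, n_components: int = 2
) -> Embedding:
    """PCA of cells on centered log values over a gene subset.

    Sign convention: each component is oriented so its largest-magnitude
    gene loading is positive, making the embedding deterministic.
    """
    gene_subset = np.asarray(gene_subset)
    if gene_subset.dtype == bool:
        gene_subset = np.flatnonzero(gene_subset)
    if len(gene_subset) == 0:
        raise ValidationError("gene_subset is empty")
    X = nm.log_values[gene_subset].T  # cells x genes
    if n_components > min(X.shape):
        raise ValidationError("n_components exceeds min(genes, cells)")
    if np.allclose(X.var(axis=0), 0):
        raise EstimationError("constant matrix: zero variance, PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    for c in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[c])))
        if pca.components_[c, j] < 0:
            coords[:, c] *= -1.0
    return Embedding(
        coordinates=coords,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X, clipped to [0, 2]."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    sd[sd == 0] = 1.0
    C = (Xc / sd[:, None]) @ (Xc / sd[:, None]).T
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def cluster_cells(
    nm: NormalizedMatrix,
    hvg_set: np.ndarray,
    K: int | None = None,
    max_clusters: int = 8,
) -> SubgroupAssignment:
    """Hierarchical clustering of cells over HVG log values."""
    hvg_set = np.asarray(hvg_set)
    if hvg_set.dtype == bool:
        hvg_set = np.flatnonzero(hvg_set)
    if len(hvg_set) < 2:
        raise ValidationError("need at least 2 HVGs to cluster cells")
    if nm.n_cells < 3:
        raise ValidationError("need at least 3 cells to cluster")
    # standardize each gene across cells so cell-cell correlation reflects
    # relative expression patterns, not the shared baseline profile
    G = nm.log_values[hvg_set]
    sd = G.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = ((G - G.mean(axis=1, keepdims=True)) / sd).T  # cells x genes
    D = _correlation_distance(X)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    if K is not None:
        if K < 1:
            raise ValidationError("K must be >= 1")
        labels = (
            np.ones(nm.n_cells, dtype=int)
            if K == 1
            else hierarchy.fcluster(Z, t=K, criterion="maxclust")
        )
    else:
        best, best_score = 2, -np.inf
        upper = min(max_clusters, nm.n_cells - 1)
        for k in range(2, upper + 1):
            cand = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(cand)) < 2:
                continue
            score = silhouette_score(D, cand, metric="precomputed")
            if score > best_score:
                best, best_score = k, score
        labels = hierarchy.fcluster(Z, t=best, criterion="maxclust")
    # relabel 1..K by decreasing group size (ties by first occurrence)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[v] for v in labels], dtype=int)
    return SubgroupAssignment(labels=labels, K=len(uniq), linkage_tree=Z)
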