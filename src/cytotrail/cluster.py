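"""Clustering, cluster-dependent downsampling and dimensionality reduction.

Clustering assigns every cell a label in ``1..K`` (SOM grid node,
k-means or Ward hierarchical cluster).  Downsampling is performed within
each cluster separately so rare populations are never dropped entirely.
Embeddings (PCA / tSNE / diffusion map / UMAP) are computed either per
kept cell or on the cluster centroids; centroids are plain arithmetic
means of member cells in the chosen space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from cytotrail.model import CytoState
from cytotrail.som import som_fit

#: refuse cell-level nonlinear embeddings above this size unless forced
CELL_EMBED_GUARD = 100_000


@dataclass
class ClusterTable:
    """Per-cluster summary: sizes, expression centroids, embedding centroids."""

    cluster_ids: list[int]
    sizes: np.ndarray
    centroid_expression: np.ndarray              # clusters x markers
    centroid_embedding: dict = field(default_factory=dict)  # name -> clusters x dims
    branch_labels: Optional[np.ndarray] = None   # per-cluster

    def __post_init__(self) -> None:
        if len(self.cluster_ids) != len(self.sizes):
            raise ValueError("sizes must align with cluster_ids")
        if self.centroid_expression.shape[0] != len(self.cluster_ids):
            raise ValueError("centroid rows must align with cluster_ids")


def run_cluster(
    state: CytoState,
    method: str = "som",
    seed: int = 0,
    xdim: int = 6,
    ydim: int = 6,
    rlen: int = 8,
    k: Optional[int] = None,
    custom: Optional[callable] = None,
) -> CytoState:
    """Cluster all cells; labels land in ``state.cluster_labels`` (1-based).

    ``method`` is ``som`` (default, 6x6 grid), ``kmeans``, ``hclust``
    (Ward linkage, Euclidean) or ``custom`` with a callable mapping the
    cells x markers matrix to integer labels — the plug-in route for
    algorithms such as clara or PhenoGraph.

    Re-clustering invalidates every downstream result.
    """
    data = state.matrix.values
    n = data.shape[0]
    if method == "som":
        result = som_fit(data, xdim=xdim, ydim=ydim, rlen=rlen, seed=seed)
        labels = result.labels + 1
        params = {"xdim": xdim, "ydim": ydim, "rlen": rlen}
    elif method in ("kmeans", "hclust"):
        if k is None:
            raise ValueError(f"{method} requires k")
        if k < 2 or k > n:
            raise ValueError(f"k={k} must be in [2, {n}]")
        if method == "kmeans":
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
            labels = km.fit_predict(data) + 1
        else:
            from sklearn.cluster import AgglomerativeClustering

            hc = AgglomerativeClustering(n_clusters=k, linkage="ward")
            labels = hc.fit_predict(data) + 1
        params = {"k": k}
    elif method == "custom":
        if custom is None:
            raise ValueError("method 'custom' requires the custom= callable")
        labels = np.asarray(custom(data), dtype=int)
        if labels.shape != (n,):
            raise ValueError("custom clusterer must return one label per cell")
        params = {"callable": getattr(custom, "__name__", "custom")}
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    state.invalidate("cluster")
    state.cluster_labels = np.asarray(labels, dtype=int)
    state.record("run_cluster", method=method, seed=seed, **params)
    return state


def cluster_downsample(state: CytoState, fraction: float, seed: int = 0) -> CytoState:
    """Keep ``max(1, ceil(fraction * size))`` cells per cluster.

    Sampling is uniform without replacement within each cluster, with a
    deterministic substream per cluster id, so no cluster — however small —
    is ever emptied.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = state.require("cluster_labels", "cluster_downsample")
    mask = np.zeros(state.n_cells, dtype=bool)
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        n_keep = max(1, math.ceil(fraction * members.size))
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(cid)]))
        mask[rng.choice(members, size=n_keep, replace=False)] = True
    state.invalidate("downsample")
    state.kept_mask = mask
    state.record("cluster_downsample", fraction=fraction, seed=seed, kept=int(mask.sum()))
    return state


def diffusion_map(
    matrix: np.ndarray, ndim: int = 2, sigma: float | str = "auto", seed: int = 0
) -> np.ndarray:
    """Diffusion-map embedding of the rows of ``matrix``.

    A Gaussian kernel ``K_ij = exp(-d_ij^2 / (2 sigma^2))`` is density-
    normalised (dividing by the product of row sums, removing sampling-
    density bias) and row-normalised into a Markov transition matrix; the
    coordinates are the top non-trivial right eigenvectors scaled by their
    eigenvalues.  ``sigma='auto'`` uses the median pairwise distance.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < ndim + 2:
        raise ValueError(f"need at least {ndim + 2} rows for {ndim} diffusion components")
    d = pdist(matrix)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite pairwise distances")
    if sigma == "auto":
        sigma = float(np.median(d))
        if sigma == 0:
            sigma = 1.0
    d2 = squareform(d) ** 2
    kernel = np.exp(-d2 / (2.0 * float(sigma) ** 2))
    # density normalisation (alpha = 1)
    q = kernel.sum(axis=1)
    kernel = kernel / np.outer(q, q)
    row = kernel.sum(axis=1)
    # symmetric conjugate of the Markov matrix for a stable eigensolve
    inv_sqrt = 1.0 / np.sqrt(row)
    sym = kernel * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov matrix; drop the trivial constant one
    psi = evecs * inv_sqrt[:, None]
    coords = psi[:, 1 : ndim + 1] * evals[1 : ndim + 1][None, :]
    # fix sign for determinism: largest-magnitude entry positive
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return coords


def run_dimred(
    state: CytoState,
    method: str = "umap",
    ndim: int = 2,
    seed: int = 0,
    level: str = "cells",
    sigma: float | str = "auto",
    force: bool = False,
) -> CytoState:
    """Embed kept cells (``level='cells'``) or cluster centroids.

    PCA is an exact centred SVD; tSNE and UMAP are seeded; the diffusion
    map follows :func:`diffusion_map`.  Cell-level tSNE/UMAP/dm refuse to
    run above 100,000 kept cells unless ``force=True`` — downsample first.
    """
    if level == "cells":
        idx = state.kept_indices()
        data = state.matrix.values[idx]
    elif level == "clusters":
        table = state.require("cluster_table", "run_dimred(level='clusters')")
        data = table.centroid_expression
    else:
        raise ValueError("level must be 'cells' or 'clusters'")

    n, p = data.shape
    if level == "cells" and method != "pca" and n > CELL_EMBED_GUARD and not force:
        raise RuntimeError(
            f"{n} cells exceeds the {CELL_EMBED_GUARD} guard for cell-level {method}; "
            "downsample first or pass force=True"
        )

    if method == "pca":
        if ndim >= p:
            raise ValueError(f"PCA ndim={ndim} must be < feature count {p}")
        from sklearn.decomposition import PCA

        coords = PCA(n_components=ndim, svd_solver="full").fit_transform(data)
        # deterministic sign convention
        for j in range(coords.shape[1]):
            i = int(np.argmax(np.abs(coords[:, j])))
            if coords[i, j] < 0:
                coords[:, j] *= -1
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
        coords = TSNE(
            n_components=ndim, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(data)
    elif method == "umap":
        import umap

        n_neighbors = min(15, max(2, n - 1))
        coords = umap.UMAP(
            n_components=ndim, random_state=seed, n_neighbors=n_neighbors
        ).fit_transform(data)
    elif method == "dm":
        coords = diffusion_map(data, ndim=ndim, sigma=sigma, seed=seed)
    else:
        raise ValueError(f"unknown dimensionality reduction {method!r}")

    coords = np.asarray(coords, dtype=float)
    if level == "cells":
        state.embeddings[method] = coords
    else:
        table = state.cluster_table
        table.centroid_embedding[method] = coords
    state.record("run_dimred", method=method, ndim=ndim, seed=seed, level=level)
    return state


def cluster_coordinates(state: CytoState, space: str = "expression") -> ClusterTable:
    """Cluster centroids as per-cluster arithmetic means.

    In expression space the centroid of cluster *j* on marker *i* is the
    mean of that marker over all of the cluster's cells; in an embedding
    space it is the mean coordinate over the cluster's kept cells.  The
    resulting table is stored on the state and returned.
    """
    labels = state.require("cluster_labels", "cluster_coordinates")
    cluster_ids = [int(c) for c in np.unique(labels)]

    sizes = np.array([int((labels == c).sum()) for c in cluster_ids])
    expr = state.matrix.values
    centroid_expr = np.vstack([expr[labels == c].mean(axis=0) for c in cluster_ids])

    if state.cluster_table is None:
        state.cluster_table = ClusterTable(
            cluster_ids=cluster_ids, sizes=sizes, centroid_expression=centroid_expr
        )
    table = state.cluster_table

    if space != "expression":
        if space not in state.embeddings:
            raise KeyError(f"embedding {space!r} not computed; have {sorted(state.embeddings)}")
        kept = state.kept_indices()
        kept_labels = labels[kept]
        coords = state.embeddings[space]
        rows = []
        for c in cluster_ids:
            members = kept_labels == c
            if not members.any():
                raise ValueError(
                    f"cluster {c} has no kept cells; lower the downsampling or re-sample"
                )
            rows.append(coords[members].mean(axis=0))
        table.centroid_embedding[space] = np.vstack(rows)

    state.record("cluster_coordinates", space=space)
    return table
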