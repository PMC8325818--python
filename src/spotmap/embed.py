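"""Normalization, PCA reporting, RGB embeddings and de novo clustering of
segmented count matrices.

Counts are normalized per gene (each gene column divided by its total) so
highly expressed genes do not dominate the distance structure; an optional
per-unit total normalization is available but not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SegmentedMap

__all__ = [
    "NormalizedMatrix",
    "EmbeddingResult",
    "ClusterAssignment",
    "normalize_by_gene_totals",
    "pca_report",
    "rgb_embedding",
    "cluster",
    "cluster_summaries",
]


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # units × genes, real
    method: str
    params: dict


@dataclass
class EmbeddingResult:
    """Three retained dimensions per unit plus their RGB rendering.

    Each RGB channel is min-max scaled to span exactly [0, 1] over units.
    """

    scores: pd.DataFrame  # units × 3
    rgb: np.ndarray  # (units, 3) in [0, 1]
    loadings: pd.DataFrame | None
    method: str
    seed: int


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-unit cluster id; -1 = DBSCAN noise
    method: str
    params: dict
    seed: int


def normalize_by_gene_totals(
    seg: SegmentedMap, *, per_unit: bool = False
) -> NormalizedMatrix:
    """Divide each gene column by its total count, so columns sum to 1.

    Requires every gene to have a positive total (run qc_filter first).
    ``per_unit=True`` instead divides each row by its total.
    """
    counts = seg.counts.astype(float)
    if per_unit:
        tot = counts.sum(axis=1)
        if (tot == 0).any():
            raise ValueError("unit(s) with zero reads; run qc_filter first")
        vals = counts.div(tot, axis=0)
        return NormalizedMatrix(vals, "per_unit_total", {})
    tot = counts.sum(axis=0)
    if (tot == 0).any():
        zero = list(tot.index[tot == 0])
        raise ValueError(f"gene(s) with zero total {zero}; run qc_filter first")
    return NormalizedMatrix(counts.div(tot, axis=1), "per_gene_total", {})


def _loading_sign_flips(components: np.ndarray) -> np.ndarray:
    """±1 per component making its largest-magnitude loading positive."""
    flip = np.sign(components[np.arange(len(components)),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return flip


def pca_report(
    mat: NormalizedMatrix, n_components: int = 20
) -> dict:
    """Centered PCA: scores, loadings and variance explained.

    Loadings follow a sign convention (largest-magnitude loading per
    component positive) for run-to-run reproducibility.
    """
    from sklearn.decomposition import PCA

    x = mat.values.to_numpy(float)
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix has no principal components")
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    flip = _loading_sign_flips(pca.components_)
    comps = pca.components_ * flip[:, None]
    scores = scores * flip[None, :]  # keeps scores @ loadings unchanged
    names = [f"PC{i + 1}" for i in range(n_components)]
    return {
        "scores": pd.DataFrame(scores, index=mat.values.index, columns=names),
        "loadings": pd.DataFrame(comps, index=names, columns=mat.values.columns),
        "variance_ratio": pd.Series(pca.explained_variance_ratio_, index=names),
    }


def _minmax(cols: np.ndarray) -> np.ndarray:
    lo = cols.min(axis=0)
    rng = cols.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (cols - lo) / rng


def rgb_embedding(
    mat: NormalizedMatrix,
    method: str = "pca",
    *,
    seed: int = 0,
    pca_init: int | None = None,
    **method_params,
) -> EmbeddingResult:
    """Three-dimensional embedding of units rendered as RGB.

    ``method`` is one of ``pca`` (top-3 PCs), ``tsne`` or ``umap`` (run
    directly at 3 output dimensions; ``pca_init`` optionally pre-reduces
    to that many PCs first).  Each of the three axes is min-max scaled to
    [0, 1] independently, giving every unit an RGB triple for spatial maps.
    """
    x = mat.values.to_numpy(float)
    if len(x) < 4:
        raise ValueError("need at least 4 units to embed")
    if pca_init is not None and method != "pca":
        from sklearn.decomposition import PCA

        x = PCA(n_components=min(pca_init, min(x.shape)),
                svd_solver="full").fit_transform(x)
    loadings = None
    if method == "pca":
        rep = pca_report(mat, n_components=3)
        scores = rep["scores"].to_numpy()
        loadings = rep["loadings"]
    elif method == "tsne":
        from sklearn.manifold import TSNE

        params = dict(perplexity=min(30.0, (len(x) - 1) / 3.0), init="pca")
        params.update(method_params)
        scores = TSNE(n_components=3, random_state=seed, **params).fit_transform(x)
    elif method == "umap":
        import umap

        scores = umap.UMAP(
            n_components=3, random_state=seed, **method_params
        ).fit_transform(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = [f"dim{i + 1}" for i in range(3)]
    return EmbeddingResult(
        scores=pd.DataFrame(scores, index=mat.values.index, columns=cols),
        rgb=_minmax(np.asarray(scores, float)),
        loadings=loadings,
        method=method,
        seed=seed,
    )


def cluster(
    mat: NormalizedMatrix,
    method: str = "kmeans",
    *,
    k: int | None = None,
    seed: int = 0,
    **method_params,
) -> ClusterAssignment:
    """Cluster units with k-means, Ward hierarchical, or DBSCAN.

    k-means and hierarchical require ``k``; DBSCAN instead takes ``eps``
    and ``min_samples`` via ``method_params`` and may emit a noise label
    (-1).  Results are deterministic given the seed.
    """
    x = mat.values.to_numpy(float)
    if method in ("kmeans", "hierarchical"):
        if k is None or k < 2:
            raise ValueError("k >= 2 required")
        if k > len(x):
            raise ValueError(f"k={k} exceeds {len(x)} units")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, random_state=seed, n_init=10,
                        **method_params).fit_predict(x)
    elif method == "hierarchical":
        from sklearn.cluster import AgglomerativeClustering

        labels = AgglomerativeClustering(
            n_clusters=k, linkage="ward", **method_params
        ).fit_predict(x)
    elif method == "dbscan":
        from sklearn.cluster import DBSCAN

        labels = DBSCAN(**method_params).fit_predict(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ClusterAssignment(
        labels=np.asarray(labels), method=method,
        params={"k": k, **method_params}, seed=seed,
    )


def cluster_summaries(
    assign: ClusterAssignment,
    seg: SegmentedMap,
    *,
    normalized: NormalizedMatrix | None = None,
) -> pd.DataFrame:
    """Cluster × gene mean expression (raw counts, or a normalized matrix
    when given).  Empty clusters get a zero row with a warning."""
    vals = (normalized.values if normalized is not None else seg.counts).astype(float)
    if len(vals) != len(assign.labels):
        raise ValueError("assignment not aligned to segmented map rows")
    df = vals.copy()
    df["_cluster"] = assign.labels
    means = df.groupby("_cluster").mean()
    means.index.name = "cluster"
    return means
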