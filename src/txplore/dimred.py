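"""Sample-space embeddings (PCA, classical MDS, t-SNE/UMAP) and
hierarchical leaf ordering for heatmaps.

Samples (sequencing libraries) are the observations and genes the
features, matching how expression libraries are compared; pass
``transpose=True`` to embed genes instead. PCA and classical MDS are
computed natively (SVD of the centered matrix; double-centering plus
eigendecomposition); t-SNE and UMAP are delegated to scikit-learn and
umap-learn with a contract of shape, determinism-given-seed, and cluster
preservation.

PCA components follow a fixed sign convention — the largest-|loading|
entry of each component is positive — so coordinates are stable across
platforms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import DataError, ExpressionMatrix, LOG_UNIT

__all__ = [
    "pca",
    "classical_mds",
    "embed_nonlinear",
    "hierarchical_order",
    "EmbeddingResult",
    "HeatmapOrder",
]


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates keyed by sample (or gene) identifier."""

    coordinates: pd.DataFrame  # items × k
    method: str
    explained_variance_ratio: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None
    negative_eigenvalue_mass: float | None = None  # classical MDS only
    n_dropped_constant_features: int = 0


def _observation_matrix(matrix: ExpressionMatrix, transpose: bool):
    if transpose:
        return matrix.data.to_numpy(dtype=float), matrix.gene_ids
    if matrix.unit != LOG_UNIT:
        warnings.warn(
            f"embedding a {matrix.unit!r} matrix; log2 input is recommended",
            UserWarning,
            stacklevel=3,
        )
    return matrix.data.to_numpy(dtype=float).T, matrix.sample_ids


def _fix_signs(coords: np.ndarray, loadings: np.ndarray):
    """Make the largest-|loading| entry of each component positive."""
    for j in range(loadings.shape[0]):
        pivot = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, pivot] < 0:
            loadings[j] *= -1.0
            coords[:, j] *= -1.0
    return coords, loadings


def pca(
    matrix: ExpressionMatrix,
    k: int = 2,
    scale: bool = False,
    transpose: bool = False,
) -> EmbeddingResult:
    """Principal component analysis of samples in gene space.

    Features are centered (and optionally scaled to unit variance;
    constant features are dropped with a count). Decomposition is by
    singular values of the centered observation matrix; explained
    variance fractions are relative to the total variance of the kept
    features.
    """
    x, ids = _observation_matrix(matrix, transpose)
    n = x.shape[0]
    if n < 2:
        raise DataError("PCA requires at least 2 observations")
    xc = x - x.mean(axis=0)
    n_dropped = 0
    if scale:
        sd = xc.std(axis=0, ddof=1)
        keep = sd > 0
        n_dropped = int((~keep).sum())
        xc = xc[:, keep] / sd[keep]
    if k < 1 or k > min(n, xc.shape[1]):
        raise DataError(
            f"k={k} out of range 1..{min(n, xc.shape[1])} for this matrix"
        )
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    coords = u[:, :k] * s[:k]
    coords, _ = _fix_signs(coords, vt[:k].copy())
    total = float((s**2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(
        coordinates=frame,
        method="pca",
        explained_variance_ratio=evr,
        params={"k": k, "scale": scale, "transpose": transpose},
        n_dropped_constant_features=n_dropped,
    )


def classical_mds(
    distances, k: int = 2, ids: list[str] | None = None
) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers B = -1/2 J D^2 J and embeds with the top-k
    nonnegative eigenpairs; the mass of negative eigenvalues is reported
    as a distortion fraction (zero for exact Euclidean input).
    """
    if isinstance(distances, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    n = d.shape[0]
    if ids is None:
        ids = [f"item{i + 1}" for i in range(n)]
    if np.abs(d - d.T).max() > 1e-8:
        raise DataError("distance matrix is not symmetric (tolerance 1e-8)")
    if np.abs(np.diag(d)).max() > 1e-8:
        raise DataError("distance matrix diagonal must be zero")
    if (d < 0).any():
        raise DataError("distances must be nonnegative")
    if k < 1 or k > n:
        raise DataError(f"k={k} out of range 1..{n}")
    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    total_mass = float(np.abs(eigvals).sum())
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    neg_fraction = neg_mass / total_mass if total_mass > 0 else 0.0
    lam = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(lam)
    coords, _ = _fix_signs(coords, eigvecs[:, :k].T.copy())
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"MDS{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(
        coordinates=frame,
        method="mds",
        params={"k": k},
        negative_eigenvalue_mass=neg_fraction,
    )


def embed_nonlinear(
    matrix: ExpressionMatrix,
    method: str = "tsne",
    k: int = 2,
    seed: int = 0,
    neighborhood: float | None = None,
    transpose: bool = False,
) -> EmbeddingResult:
    """t-SNE or UMAP embedding, delegated to the reference implementations.

    ``neighborhood`` is the t-SNE perplexity (default 30) or the UMAP
    neighbor count (default 15); it must be smaller than the number of
    observations. Identical inputs and seed give identical coordinates.
    """
    if method not in ("tsne", "umap"):
        raise DataError(f"unknown embedding method {method!r}")
    if k not in (2, 3):
        raise DataError("nonlinear embeddings support k in {2, 3}")
    x, ids = _observation_matrix(matrix, transpose)
    n = x.shape[0]
    if method == "tsne":
        perplexity = 30.0 if neighborhood is None else float(neighborhood)
        if perplexity <= 0 or perplexity >= n:
            raise DataError(
                f"perplexity must be in (0, n_observations); got {perplexity} "
                f"with {n} observations — lower it (e.g. (n-1)/3)"
            )
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=k,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(x)
        params = {"perplexity": perplexity}
    else:
        n_neighbors = 15 if neighborhood is None else int(neighborhood)
        if n_neighbors < 2 or n_neighbors >= n:
            raise DataError(
                f"n_neighbors must be in [2, n_observations); got {n_neighbors} "
                f"with {n} observations — lower it"
            )
        import umap  # deferred: numba compilation makes this import heavy

        coords = umap.UMAP(
            n_components=k, n_neighbors=n_neighbors, random_state=seed
        ).fit_transform(x)
        params = {"n_neighbors": n_neighbors}
    frame = pd.DataFrame(
        np.asarray(coords, dtype=float),
        index=ids,
        columns=[f"{method.upper()}{i + 1}" for i in range(k)],
    )
    return EmbeddingResult(
        coordinates=frame, method=method, params={**params, "k": k}, seed=seed
    )


@dataclass
class HeatmapOrder:
    gene_order: list[str]
    sample_order: list[str]
    linkage: str
    distance: str


def _correlation_distances(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; constant rows are distance 1 to all."""
    sd = rows.std(axis=1)
    constant = sd == 0
    n = rows.shape[0]
    d = np.ones((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        r = np.corrcoef(rows[ok])
        d[np.ix_(ok, ok)] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # guard tiny negative values from float error
    return np.clip(d, 0.0, None)


def hierarchical_order(
    matrix: ExpressionMatrix,
    axis: str = "genes",
    distance: str = "correlation",
    linkage: str = "average",
) -> HeatmapOrder:
    """Agglomerative leaf order along one axis for heatmap display."""
    if axis not in ("genes", "samples"):
        raise DataError("axis must be 'genes' or 'samples'")
    if distance not in ("correlation", "euclidean"):
        raise DataError("distance must be 'correlation' or 'euclidean'")
    if linkage not in ("average", "complete"):
        raise DataError("linkage must be 'average' or 'complete'")
    values = matrix.data.to_numpy(dtype=float)
    if axis == "samples":
        values = values.T
        ids = matrix.sample_ids
    else:
        ids = matrix.gene_ids
    if len(ids) == 1:
        order = ids
    else:
        if distance == "correlation":
            condensed = squareform(_correlation_distances(values), checks=False)
        else:
            condensed = pdist(values, metric="euclidean")
        link = hierarchy.linkage(condensed, method=linkage)
        order = [ids[i] for i in hierarchy.leaves_list(link)]
    if axis == "genes":
        return HeatmapOrder(order, matrix.sample_ids, linkage, distance)
    return HeatmapOrder(matrix.gene_ids, order, linkage, distance)
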