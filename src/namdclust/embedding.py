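"""Dimensionality reduction: PCA, ISOMAP, and t-SNE.

All three map a frame-indexed feature table to an n x d coordinate matrix
carrying the same keys.  PCA and t-SNE stand on scikit-learn; ISOMAP is
assembled from its textbook parts — a union-symmetrized k-nearest-neighbor
graph with Euclidean edge weights, all-pairs shortest paths (Dijkstra), and
classical MDS on the double-centered squared geodesic distances — so the
graph-connectivity contract can be enforced explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import kneighbors_graph

from .exceptions import ConfigError, ConnectivityError

__all__ = ["Embedding", "pca_fit_transform", "isomap_fit_transform", "tsne_fit_transform"]


@dataclass
class Embedding:
    """Low-dimensional coordinates for a set of frames.

    ``meta`` carries method-specific diagnostics: explained-variance ratios
    for PCA, the clamped-eigenvalue residual for ISOMAP, the final KL
    divergence for t-SNE.
    """

    keys: pd.MultiIndex
    coords: np.ndarray  # (n, d)
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"X{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.coords, index=self.keys, columns=cols)


def _as_matrix(t: pd.DataFrame) -> tuple[pd.MultiIndex, np.ndarray]:
    return t.index, t.to_numpy(dtype=float)


def pca_fit_transform(t: pd.DataFrame, n_components: int = 2) -> Embedding:
    """Principal component analysis of a feature table.

    Components are ordered by decreasing explained variance, and each
    component's sign is fixed so its largest-magnitude loading is positive
    (bit-stable across runs).
    """
    keys, x = _as_matrix(t)
    if not 1 <= n_components <= min(x.shape[0] - 1, x.shape[1]):
        raise ConfigError(
            f"n_components={n_components} outside [1, min(rows-1, cols)="
            f"{min(x.shape[0] - 1, x.shape[1])}]"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x)
    components = model.components_.copy()
    for k in range(n_components):
        imax = int(np.argmax(np.abs(components[k])))
        if components[k, imax] < 0:
            components[k] *= -1.0
            coords[:, k] *= -1.0
    return Embedding(
        keys,
        coords,
        "pca",
        meta={
            "explained_variance_ratio": model.explained_variance_ratio_.copy(),
            "components": components,
            "mean": model.mean_.copy(),
        },
    )


def isomap_fit_transform(
    t: pd.DataFrame, n_neighbors: int = 30, n_components: int = 2
) -> Embedding:
    """ISOMAP embedding preserving graph-geodesic distances.

    The k-NN graph is symmetrized by union with Euclidean edge weights;
    geodesics are Dijkstra shortest paths; coordinates come from classical
    MDS of the double-centered squared geodesic matrix, with negative
    eigenvalues clamped to zero (their total magnitude is reported in
    ``meta['residual']``).  A disconnected graph raises
    :class:`ConnectivityError` naming the component sizes.
    """
    keys, x = _as_matrix(t)
    n = x.shape[0]
    if n_neighbors < 1 or n_neighbors >= n:
        raise ConfigError(f"n_neighbors={n_neighbors} outside [1, rows-1]")
    if not 1 <= n_components <= n - 1:
        raise ConfigError("n_components outside [1, rows-1]")
    graph = kneighbors_graph(x, n_neighbors=n_neighbors, mode="distance")
    graph = graph.maximum(graph.T)  # union symmetrization
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ConnectivityError(
            f"neighborhood graph has {n_comp} components of sizes {sizes}; "
            f"increase n_neighbors"
        )
    geo = dijkstra(graph, directed=False)
    d2 = geo**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    residual = float(np.abs(evals[evals < 0]).sum())
    top = np.clip(evals[:n_components], 0.0, None)
    coords = evecs[:, :n_components] * np.sqrt(top)
    return Embedding(
        keys,
        coords,
        "isomap",
        meta={"residual": residual, "eigenvalues": evals[:n_components].copy()},
    )


def tsne_fit_transform(
    t: pd.DataFrame,
    perplexity: float = 30.0,
    n_components: int = 2,
    seed: int = 0,
) -> Embedding:
    """t-SNE embedding, deterministic for a fixed seed.

    The conventional guard ``perplexity < rows/3`` is enforced;
    ``meta['kl_divergence']`` carries the final objective value.
    """
    keys, x = _as_matrix(t)
    if perplexity <= 0 or perplexity >= x.shape[0] / 3.0:
        raise ConfigError(
            f"perplexity={perplexity} must be in (0, rows/3={x.shape[0] / 3.0:g})"
        )
    model = TSNE(
        n_components=n_components,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    )
    coords = model.fit_transform(x)
    return Embedding(
        keys,
        np.asarray(coords, dtype=float),
        "tsne",
        meta={"kl_divergence": float(model.kl_divergence_)},
    )
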