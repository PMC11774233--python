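"""Conformational clustering and cluster-number selection.

Four partitioners over descriptor space — K-means, Gaussian mixtures,
hierarchical agglomerative, and spectral clustering — plus the two quality
metrics (silhouette, Calinski–Harabasz) and a "best"-k selector that ranks
candidate cluster counts by both metrics and returns the k with the lowest
summed rank (ties broken toward the smallest k).

K-means/GMM/spectral delegate to scikit-learn, the hierarchical dendrogram
to scipy; labels are 0-based and label identity is arbitrary, so any
comparison against ground truth should use a permutation-invariant score
such as the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.mixture import GaussianMixture

from .exceptions import ConfigError, DataError, NumericalError

__all__ = [
    "ClusterResult",
    "kmeans",
    "gmm",
    "hierarchical",
    "spectral",
    "silhouette",
    "calinski_harabasz",
    "select_k_best",
    "kmeans_inertia_trace",
    "gmm_loglik_trace",
]

#: guard for zero within-cluster dispersion in Calinski-Harabasz
_EPS_WITHIN = 1e-12


@dataclass
class ClusterResult:
    """A hard partition of frames plus model parameters and quality metrics.

    ``labels`` are 0-based cluster ids aligned with ``keys``; ``model``
    holds method-specific parameters (centroids, mixture parameters and
    responsibilities, the merge dendrogram, ...); ``metrics`` holds the
    silhouette and Calinski–Harabasz scores when defined (2 <= k <= n-1).
    """

    keys: pd.MultiIndex
    labels: np.ndarray
    k: int
    method: str
    model: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels}, index=self.keys)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _as_matrix(t: pd.DataFrame) -> tuple[pd.MultiIndex, np.ndarray]:
    return t.index, t.to_numpy(dtype=float)


def _attach_metrics(result: ClusterResult, x: np.ndarray) -> ClusterResult:
    n = x.shape[0]
    if 2 <= result.k <= n - 1 and len(np.unique(result.labels)) == result.k:
        result.metrics["silhouette"] = silhouette_from_matrix(x, result.labels)
        result.metrics["calinski_harabasz"] = calinski_from_matrix(x, result.labels)
    return result


def kmeans(t: pd.DataFrame, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's K-means with k-means++ seeding, 10 restarts, tol 1e-4."""
    keys, x = _as_matrix(t)
    if not 1 <= k <= x.shape[0]:
        raise DataError(f"k={k} outside [1, rows={x.shape[0]}]")
    model = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        tol=1e-4,
        max_iter=300,
        random_state=seed,
    ).fit(x)
    result = ClusterResult(
        keys,
        model.labels_.astype(int),
        k,
        "kmeans",
        model={"centroids": model.cluster_centers_.copy(), "inertia": float(model.inertia_)},
    )
    return _attach_metrics(result, x)


def gmm(t: pd.DataFrame, k: int, seed: int = 0) -> ClusterResult:
    """Gaussian mixture via EM: full covariances, reg 1e-6, k-means init.

    Hard labels are the argmax responsibilities; the per-row responsibility
    matrix is retained in ``model['responsibilities']``.
    """
    keys, x = _as_matrix(t)
    if x.shape[0] <= k:
        raise DataError(f"GMM needs more rows than components (rows={x.shape[0]}, k={k})")
    model = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        tol=1e-3,
        init_params="kmeans",
        random_state=seed,
    )
    try:
        model.fit(x)
    except np.linalg.LinAlgError as exc:  # singular covariance despite reg
        raise NumericalError(f"GMM covariance became singular: {exc}") from exc
    resp = model.predict_proba(x)
    result = ClusterResult(
        keys,
        resp.argmax(axis=1).astype(int),
        k,
        "gmm",
        model={
            "weights": model.weights_.copy(),
            "means": model.means_.copy(),
            "covariances": model.covariances_.copy(),
            "responsibilities": resp,
            "log_likelihood": float(model.score(x) * x.shape[0]),
        },
    )
    return _attach_metrics(result, x)


def hierarchical(t: pd.DataFrame, k: int, linkage: str = "ward") -> ClusterResult:
    """Agglomerative clustering; the dendrogram is cut at ``k`` clusters.

    Default linkage is Ward with Euclidean distances; ``average``,
    ``complete`` and ``single`` are also accepted.  Fully deterministic.
    """
    keys, x = _as_matrix(t)
    if linkage not in ("ward", "average", "complete", "single"):
        raise ConfigError(f"unknown linkage {linkage!r}")
    if not 1 <= k <= x.shape[0]:
        raise DataError(f"k={k} outside [1, rows={x.shape[0]}]")
    z = scipy_linkage(x, method=linkage, metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)  # 0-based, compact
    result = ClusterResult(keys, labels.astype(int), k, "hierarchical",
                           model={"dendrogram": z, "linkage": linkage})
    return _attach_metrics(result, x)


def spectral(t: pd.DataFrame, k: int, seed: int = 0) -> ClusterResult:
    """Spectral clustering on an RBF affinity (gamma = 1/n_features).

    Builds the symmetric normalized Laplacian, takes the bottom-k
    eigenvectors, row-normalizes them, and runs K-means in that spectral
    embedding.
    """
    keys, x = _as_matrix(t)
    n, n_features = x.shape
    if n <= k:
        raise DataError(f"spectral clustering needs rows > k (rows={n}, k={k})")
    affinity = rbf_kernel(x, gamma=1.0 / n_features)
    row_sums = affinity.sum(axis=1)
    if np.any(row_sums <= 0):
        raise NumericalError("degenerate affinity: a row of the kernel matrix is zero")
    d_inv_sqrt = 1.0 / np.sqrt(row_sums)
    lap = np.eye(n) - d_inv_sqrt[:, None] * affinity * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh((lap + lap.T) / 2.0)
    emb = evecs[:, :k]
    norms = np.linalg.norm(emb, axis=1)
    emb = emb / np.where(norms > 0, norms, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    result = ClusterResult(
        keys,
        km.labels_.astype(int),
        k,
        "spectral",
        model={"laplacian_eigenvalues": evals[:k].copy()},
    )
    return _attach_metrics(result, x)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def _check_metric_labels(x: np.ndarray, labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if not 2 <= k <= x.shape[0] - 1:
        raise DataError(
            f"clustering metrics need 2 <= k <= rows-1 (got k={k}, rows={x.shape[0]})"
        )
    return k


def silhouette_from_matrix(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a)/max(a, b) over all points, in [-1, 1]."""
    _check_metric_labels(x, labels)
    return float(_sk_silhouette(x, labels))


def silhouette(t: pd.DataFrame, labels: np.ndarray) -> float:
    return silhouette_from_matrix(t.to_numpy(dtype=float), labels)


def calinski_from_matrix(x: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index: (SSB/SSW) * (n-k)/(k-1), >= 0.

    Zero within-cluster dispersion is guarded with SSW = 1e-12 so perfectly
    tight clusters give a large finite value rather than infinity.
    """
    labels = np.asarray(labels)
    k = _check_metric_labels(x, labels)
    n = x.shape[0]
    grand = x.mean(axis=0)
    ssb = ssw = 0.0
    for lab in np.unique(labels):
        xs = x[labels == lab]
        mean = xs.mean(axis=0)
        ssb += xs.shape[0] * float(((mean - grand) ** 2).sum())
        ssw += float(((xs - mean) ** 2).sum())
    return ssb / max(ssw, _EPS_WITHIN) * (n - k) / (k - 1)


def calinski_harabasz(t: pd.DataFrame, labels: np.ndarray) -> float:
    return calinski_from_matrix(t.to_numpy(dtype=float), labels)


_ALGORITHMS = {
    "kmeans": lambda t, k, seed, linkage: kmeans(t, k, seed),
    "gmm": lambda t, k, seed, linkage: gmm(t, k, seed),
    "hierarchical": lambda t, k, seed, linkage: hierarchical(t, k, linkage),
    "spectral": lambda t, k, seed, linkage: spectral(t, k, seed),
}


def run_algorithm(
    t: pd.DataFrame, algorithm: str, k: int, seed: int = 0, linkage: str = "ward"
) -> ClusterResult:
    """Uniform entry point over the four clustering algorithms."""
    if algorithm not in _ALGORITHMS:
        raise ConfigError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(_ALGORITHMS)}"
        )
    return _ALGORITHMS[algorithm](t, k, seed, linkage)


def select_k_best(
    t: pd.DataFrame,
    k_range: Iterable[int],
    algorithm: str = "kmeans",
    seed: int = 0,
    linkage: str = "ward",
) -> int:
    """Choose the cluster count combining silhouette and Calinski–Harabasz.

    Each candidate k is ranked separately under both metrics (higher is
    better, rank 1 best); the k minimizing the summed rank wins, ties going
    to the smallest k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ConfigError("empty k_range")
    if ks[0] < 2 or ks[-1] > len(t) - 1:
        raise ConfigError(f"k_range must lie within [2, rows-1], got {ks}")
    sil, cal = [], []
    for k in ks:
        res = run_algorithm(t, algorithm, k, seed=seed, linkage=linkage)
        x = t.to_numpy(dtype=float)
        sil.append(silhouette_from_matrix(x, res.labels))
        cal.append(calinski_from_matrix(x, res.labels))
    # rank 1 = best (highest score); average ranks on ties keep symmetry
    ranks = rankdata(-np.asarray(sil), method="average") + rankdata(
        -np.asarray(cal), method="average"
    )
    best = int(np.argmin(ranks))  # argmin takes the first (smallest k) on ties
    return ks[best]


# ---------------------------------------------------------------------------
# iteration traces (diagnostics for the algorithms' monotone objectives)
# ---------------------------------------------------------------------------

def kmeans_inertia_trace(
    t: pd.DataFrame, k: int, seed: int = 0, max_iter: int = 50
) -> list[float]:
    """Inertia after each Lloyd iteration from one k-means++ start.

    Lloyd's iteration can only lower the summed squared distance to the
    centroids, so the returned sequence is non-increasing.
    """
    from sklearn.cluster import kmeans_plusplus

    x = t.to_numpy(dtype=float)
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(x)), labels].sum()))
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centers[c] = x[mask].mean(axis=0)
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return trace


def gmm_loglik_trace(
    t: pd.DataFrame, k: int, seed: int = 0, max_iter: int = 50
) -> list[float]:
    """Mean log-likelihood lower bound after each EM iteration.

    Uses warm-started single-iteration fits; EM guarantees the sequence is
    non-decreasing.
    """
    x = t.to_numpy(dtype=float)
    model = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        tol=0.0,
        max_iter=1,
        init_params="kmeans",
        warm_start=True,
        random_state=seed,
    )
    trace: list[float] = []
    import warnings

    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-iteration non-convergence
            model.fit(x)
        trace.append(float(model.lower_bound_))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < 1e-12:
            break
    return trace
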