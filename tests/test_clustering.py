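"""Partitioners, quality metrics, and best-k selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from namdclust.clustering import (
    calinski_harabasz,
    gmm,
    gmm_loglik_trace,
    hierarchical,
    kmeans,
    kmeans_inertia_trace,
    select_k_best,
    silhouette,
    spectral,
)
from namdclust.exceptions import ConfigError, DataError


def _table(x):
    idx = pd.MultiIndex.from_tuples(
        [(1, float(i)) for i in range(len(x))], names=["traj", "time"]
    )
    return pd.DataFrame(np.asarray(x, dtype=float), index=idx)


def _blobs(rng, centers, n_per=50, scale=1.0):
    centers = np.asarray(centers, dtype=float)
    labels = np.repeat(np.arange(len(centers)), n_per)
    return centers[labels] + rng.normal(scale=scale, size=(len(labels), centers.shape[1])), labels


class TestKMeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        t = _table(rng.normal(size=(30, 3)))
        res = kmeans(t, 1, seed=0)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(
            res.model["centroids"][0], t.mean(axis=0), atol=1e-10
        )

    def test_two_distant_blobs_recovered(self):
        rng = np.random.default_rng(1)
        x, labels = _blobs(rng, [[0, 0], [100, 0]])
        res = kmeans(_table(x), 2, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_voronoi_property(self):
        rng = np.random.default_rng(2)
        x, _ = _blobs(rng, [[0, 0], [6, 0], [0, 6]])
        res = kmeans(_table(x), 3, seed=0)
        d = ((x[:, None, :] - res.model["centroids"][None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(d.argmin(axis=1), res.labels)

    def test_inertia_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        x, _ = _blobs(rng, [[0, 0], [4, 4], [8, 0]])
        trace = kmeans_inertia_trace(_table(x), 3, seed=1)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_oversize_k_rejected(self):
        with pytest.raises(DataError):
            kmeans(_table(np.zeros((3, 2))), 5)


class TestGMM:
    def test_responsibilities_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        x, _ = _blobs(rng, [[0, 0], [8, 0]])
        res = gmm(_table(x), 2, seed=0)
        np.testing.assert_allclose(
            res.model["responsibilities"].sum(axis=1), 1.0, atol=1e-9
        )

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        x, _ = _blobs(rng, [[0, 0], [5, 5]])
        trace = gmm_loglik_trace(_table(x), 2, seed=0)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_planted_means_recovered(self):
        rng = np.random.default_rng(6)
        x, _ = _blobs(rng, [[-5.0], [5.0]], n_per=1000)
        res = gmm(_table(x), 2, seed=0)
        means = np.sort(res.model["means"].ravel())
        np.testing.assert_allclose(means, [-5.0, 5.0], atol=0.1)

    def test_resampled_mixture_refits_to_same_means(self):
        rng = np.random.default_rng(7)
        x, _ = _blobs(rng, [[-4.0], [4.0]], n_per=500)
        res = gmm(_table(x), 2, seed=0)
        # draw from the fitted mixture and refit
        comps = rng.choice(2, p=res.model["weights"], size=1000)
        draws = np.array(
            [
                rng.normal(
                    res.model["means"][c, 0],
                    np.sqrt(res.model["covariances"][c, 0, 0]),
                )
                for c in comps
            ]
        )[:, None]
        res2 = gmm(_table(draws), 2, seed=1)
        se = 3.0 / np.sqrt(500)  # ~3 standard errors of a unit-variance mean
        np.testing.assert_allclose(
            np.sort(res2.model["means"].ravel()),
            np.sort(res.model["means"].ravel()),
            atol=3 * se + 0.05,
        )


class TestHierarchical:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(8)
        t = _table(rng.normal(size=(12, 2)))
        assert hierarchical(t, 12).k == 12
        assert len(np.unique(hierarchical(t, 12).labels)) == 12
        assert set(hierarchical(t, 1).labels) == {0}

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        t = _table(rng.normal(size=(12, 3)))
        for link in ("ward", "average", "complete", "single"):
            z = hierarchical(t, 2, linkage=link).model["dendrogram"]
            heights = z[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_single_linkage_first_merge_is_min_pairwise(self):
        """Brute-force oracle: the first merge joins the closest pair."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        np.fill_diagonal(d, np.inf)
        z = hierarchical(_table(x), 2, linkage="single").model["dendrogram"]
        assert z[0, 2] == pytest.approx(d.min(), abs=1e-12)


class TestSpectral:
    def test_concentric_rings_where_kmeans_fails(self):
        rng = np.random.default_rng(11)
        th = rng.uniform(0, 2 * np.pi, 200)
        inner = np.stack([np.cos(th[:100]), np.sin(th[:100])], axis=1)
        outer = 5.0 * np.stack([np.cos(th[100:]), np.sin(th[100:])], axis=1)
        x = np.vstack([inner, outer]) + rng.normal(scale=0.05, size=(200, 2))
        labels = np.repeat([0, 1], 100)
        spec = spectral(_table(x), 2, seed=0)
        km = kmeans(_table(x), 2, seed=0)
        assert adjusted_rand_score(labels, spec.labels) == 1.0
        assert adjusted_rand_score(labels, km.labels) < 0.9

    def test_duplicate_points_share_label(self):
        rng = np.random.default_rng(12)
        x, _ = _blobs(rng, [[0, 0], [10, 0]], n_per=20)
        x[3] = x[2]
        res = spectral(_table(x), 2, seed=0)
        assert res.labels[2] == res.labels[3]

    def test_laplacian_psd(self):
        rng = np.random.default_rng(13)
        x, _ = _blobs(rng, [[0, 0], [5, 5]], n_per=15)
        res = spectral(_table(x), 2, seed=0)
        assert np.all(res.model["laplacian_eigenvalues"] >= -1e-10)


class TestMetrics:
    def test_silhouette_tight_distant_blobs(self):
        x = np.array([[0.0, 0], [0.1, 0], [0.05, 0.1], [50, 0], [50.1, 0], [50, 0.1]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette(_table(x), labels) > 0.95

    def test_silhouette_random_labels_near_zero(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, size=200)
        assert abs(silhouette(_table(x), labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(DataError):
            silhouette(_table(np.random.default_rng(0).normal(size=(5, 2))), np.zeros(5, int))

    def test_calinski_pencil_and_paper(self):
        """{0,0} vs {10,10} in 1-D: SSB=100, SSW=eps-guarded 0."""
        x = np.array([[0.0], [0.0], [10.0], [10.0]])
        labels = np.array([0, 0, 1, 1])
        val = calinski_harabasz(_table(x), labels)
        # within = 0 -> guarded by eps = 1e-12: value = 100/1e-12 * (4-2)/(2-1)
        assert val == pytest.approx(100.0 / 1e-12 * 2.0, rel=1e-9)
        assert np.isfinite(val)

    def test_calinski_matches_sklearn_generic(self):
        rng = np.random.default_rng(15)
        x, labels = _blobs(rng, [[0, 0], [4, 1], [1, 5]], n_per=30)
        val = calinski_harabasz(_table(x), labels)
        assert val == pytest.approx(calinski_harabasz_score(x, labels), rel=1e-9)

    def test_calinski_translation_invariant(self):
        rng = np.random.default_rng(16)
        x, labels = _blobs(rng, [[0, 0], [6, 0]], n_per=20)
        a = calinski_harabasz(_table(x), labels)
        b = calinski_harabasz(_table(x + 123.4), labels)
        assert a == pytest.approx(b, rel=1e-9)


class TestSelectK:
    def test_three_planted_blobs(self):
        rng = np.random.default_rng(17)
        x, _ = _blobs(rng, [[0, 0], [30, 0], [0, 30]], n_per=40)
        assert select_k_best(_table(x), range(2, 7), seed=0) == 3

    def test_singleton_range(self):
        rng = np.random.default_rng(18)
        x, _ = _blobs(rng, [[0, 0], [10, 0]], n_per=10)
        assert select_k_best(_table(x), [2], seed=0) == 2

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigError):
            select_k_best(_table(np.zeros((10, 2))), [], seed=0)


def test_determinism_per_seed(separated_ensemble):
    from namdclust.descriptors import descriptor_dataset
    from namdclust.preprocess import resample_by_stride

    feats = resample_by_stride(descriptor_dataset(separated_ensemble, "tanh_zmat"), 0.5)
    for fn in (lambda: kmeans(feats, 3, seed=4), lambda: gmm(feats, 3, seed=4),
               lambda: spectral(feats, 3, seed=4)):
        np.testing.assert_array_equal(fn().labels, fn().labels)
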