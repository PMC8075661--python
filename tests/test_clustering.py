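"""Twice-clustering: hierarchical initialisation, K-means refinement,
Davies-Bouldin selection, centroids and occupancy ratios."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, davies_bouldin_score

from dynfc import (
    compute_dfcp_centroids,
    hierarchical_init,
    kmeans_refine,
    ratio_distributions,
    select_k_davies_bouldin,
    twice_cluster,
)
from dynfc.core import DfcTensor
from dynfc.segmentation import WqcpSample


def gaussian_clusters(rng, centers, n_per, sd):
    centers = np.asarray(centers, float)
    x = np.vstack([c + sd * rng.normal(size=(n_per, centers.shape[1])) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return x, labels


class TestHierarchicalInit:
    def test_k_equals_n_returns_samples(self, rng):
        x = rng.normal(size=(6, 3))
        centers = hierarchical_init(x, 6)
        assert sorted(map(tuple, centers)) == sorted(map(tuple, x))

    def test_separated_clouds_yield_interior_centers(self, rng):
        x, _ = gaussian_clusters(rng, [[0, 0], [100, 100]], 20, 0.5)
        centers = hierarchical_init(x, 2)
        d = np.linalg.norm(centers[:, None] - np.array([[0, 0], [100, 100]]), axis=2)
        assert sorted(d.min(axis=1) < 5) == [True, True]

    def test_duplicated_dataset_same_centers(self, rng):
        x, _ = gaussian_clusters(rng, [[0, 0], [10, 10], [0, 10]], 15, 0.3)
        c1 = hierarchical_init(x, 3)
        c2 = hierarchical_init(np.vstack([x, x]), 3)
        np.testing.assert_allclose(
            np.sort(c1, axis=0), np.sort(c2, axis=0), atol=1e-10
        )

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            hierarchical_init(rng.normal(size=(4, 2)), 5)


class TestKmeansRefine:
    def test_exact_init_converges_immediately(self, rng):
        x, truth = gaussian_clusters(rng, [[0, 0], [50, 50]], 30, 0.1)
        init = np.array([x[truth == 0].mean(0), x[truth == 1].mean(0)])
        res = kmeans_refine(x, init)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.n_iter <= 2

    def test_single_cluster_center_is_grand_mean(self, rng):
        x = rng.normal(size=(20, 4))
        res = kmeans_refine(x, x[:1])
        np.testing.assert_allclose(res.final_centers[0], x.mean(axis=0), atol=1e-10)

    def test_planted_gaussians_recovered(self):
        rng = np.random.default_rng(1)
        x, truth = gaussian_clusters(rng, [[0, 0], [10, 0], [0, 10]], 100, 0.1)
        res = twice_cluster(x, 3)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_final_inertia_not_above_initial(self, rng):
        x = rng.normal(size=(80, 5))
        init = x[rng.choice(80, 4, replace=False)]
        res = kmeans_refine(x, init)
        from scipy.spatial.distance import cdist

        d2 = cdist(x, init, "sqeuclidean")
        init_inertia = d2.min(axis=1).sum()
        assert res.inertia <= init_inertia + 1e-9

    def test_labels_are_one_based_and_full(self, rng):
        x = rng.normal(size=(30, 3))
        res = twice_cluster(x, 4)
        assert set(res.labels) == {1, 2, 3, 4}


class TestDaviesBouldinSelection:
    def test_three_separated_clusters_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, _ = gaussian_clusters(rng, [[0, 0], [30, 0], [0, 30]], 40, 0.5)
            res = select_k_davies_bouldin(x, (2, 6))
            hits += res.k == 3
        assert hits >= 9

    def test_two_clusters_beat_larger_k(self, rng):
        x, _ = gaussian_clusters(rng, [[0, 0], [40, 40]], 50, 1.0)
        res = select_k_davies_bouldin(x, (2, 4))
        assert res.db_curve[2] < res.db_curve[3]
        assert res.db_curve[2] < res.db_curve[4]

    def test_compact_clusters_score_zero(self):
        # two point-masses: zero within-cluster spread -> DB = 0
        x = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
        labels = np.array([1] * 5 + [2] * 5)
        assert davies_bouldin_score(x, labels) == 0.0

    def test_db_matches_hand_formula(self, rng):
        x, labels = gaussian_clusters(rng, [[0, 0], [5, 5], [9, 0]], 25, 1.0)
        res = twice_cluster(x, 3)
        # independent implementation of the index
        centers = np.vstack(
            [x[res.labels == c].mean(0) for c in (1, 2, 3)]
        )
        s = np.array(
            [
                np.linalg.norm(x[res.labels == c] - centers[c - 1], axis=1).mean()
                for c in (1, 2, 3)
            ]
        )
        db = 0.0
        for i in range(3):
            worst = max(
                (s[i] + s[j]) / np.linalg.norm(centers[i] - centers[j])
                for j in range(3)
                if j != i
            )
            db += worst
        db /= 3
        assert abs(davies_bouldin_score(x, res.labels) - db) < 1e-10

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            select_k_davies_bouldin(np.ones((20, 3)), (2, 4))

    def test_deterministic(self, rng):
        x = rng.normal(size=(60, 6))
        r1 = select_k_davies_bouldin(x, (2, 5))
        r2 = select_k_davies_bouldin(x, (2, 5))
        assert r1.k == r2.k
        np.testing.assert_array_equal(r1.labels, r2.labels)


def _toy_samples_and_tensors():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    b = np.zeros((3, 3))
    b[1, 2] = b[2, 1] = -0.4
    mats = np.stack([a, a, b, b])
    tensors = {"s1": DfcTensor("s1", mats, window_length=5)}
    samples = [
        WqcpSample("s1", "A", 0, 2, np.ones(3)),
        WqcpSample("s1", "A", 2, 4, np.zeros(3)),
    ]
    return a, b, tensors, samples


class TestCentroids:
    def test_identical_windows_give_that_matrix(self):
        a, _, tensors, samples = _toy_samples_and_tensors()
        res = twice_cluster(np.vstack([s.vector for s in samples]), 2)
        cents = compute_dfcp_centroids(res, samples, tensors)
        # the cluster holding the first segment averages two copies of `a`
        label_first = res.labels[0]
        (c,) = [
            c for c in cents if c.cluster == label_first and c.scope == "pooled"
        ]
        np.testing.assert_allclose(c.matrix, a)

    def test_mean_of_two_windows(self):
        a, b, tensors, _ = _toy_samples_and_tensors()
        samples = [WqcpSample("s1", "A", 1, 3, np.ones(3))]
        res = twice_cluster(np.vstack([s.vector for s in samples]), 1)
        cents = compute_dfcp_centroids(res, samples, tensors)
        pooled = [c for c in cents if c.scope == "pooled"][0]
        np.testing.assert_allclose(pooled.matrix, (a + b) / 2)

    def test_absent_scope_flagged_not_zero(self):
        _, _, tensors, samples = _toy_samples_and_tensors()
        res = twice_cluster(np.vstack([s.vector for s in samples]), 2)
        cents = compute_dfcp_centroids(res, samples, tensors)
        # no subject in group "B": every cluster's B centroid is absent
        for c in cents:
            if c.scope == "B":
                assert c.absent

    def test_pooled_is_window_weighted_group_mix(self, fitted_small):
        cents = fitted_small.centroids()
        for cluster in range(1, fitted_small.k + 1):
            per = {c.scope: c for c in cents if c.cluster == cluster}
            present = [
                per[g] for g in ("patient", "control") if not per[g].absent
            ]
            total = sum(c.n_windows_averaged for c in present)
            mix = sum(c.matrix * c.n_windows_averaged for c in present) / total
            np.testing.assert_allclose(per["pooled"].matrix, mix, atol=1e-10)


class TestRatioDistributions:
    @staticmethod
    def _result_with_labels(labels, k):
        from dynfc.clustering import TwiceClusteringResult

        return TwiceClusteringResult(
            k=k,
            labels=np.asarray(labels),
            init_centers=np.zeros((k, 2)),
            final_centers=np.zeros((k, 2)),
            inertia=0.0,
            n_iter=1,
        )

    def test_hand_counts(self):
        samples = [WqcpSample("s1", "A", i, i + 1, np.zeros(2)) for i in range(4)]
        res = self._result_with_labels([1, 1, 2, 3], 3)
        ratios = ratio_distributions(res, samples)
        np.testing.assert_allclose(ratios.ratios, [[0.5, 0.25, 0.25]])

    def test_single_sample_subject_is_one_hot(self):
        samples = [
            WqcpSample("s1", "A", 0, 1, np.zeros(2)),
            WqcpSample("s1", "A", 1, 2, np.zeros(2)),
            WqcpSample("s2", "B", 0, 1, np.zeros(2)),
        ]
        res = self._result_with_labels([1, 2, 2], 2)
        ratios = ratio_distributions(res, samples)
        np.testing.assert_allclose(ratios.ratios[1], [0.0, 1.0])

    def test_rows_sum_to_one(self, fitted_small):
        np.testing.assert_allclose(
            fitted_small.ratios.ratios.sum(axis=1), 1.0, atol=1e-9
        )
        assert np.all(fitted_small.ratios.ratios >= 0.0)
        assert np.all(fitted_small.ratios.ratios <= 1.0)
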