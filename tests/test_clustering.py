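"""Cluster models, canonical labeling, and patient aggregation rules."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from polaristroma.clustering import (
    assign_feature_average,
    assign_majority,
    fit_fcm,
    fit_gmm,
    fit_kmeans,
)


def _blobs(rng, n1=60, n2=40, sep=10.0, dim=2):
    X = np.vstack(
        [
            rng.normal(0, 0.5, size=(n1, dim)),
            rng.normal(sep, 0.5, size=(n2, dim)),
        ]
    )
    truth = np.r_[np.ones(n1), np.full(n2, 2)]
    return X, truth


class TestKMeans:
    def test_separated_masses_heavier_is_cluster_one(self, rng):
        X = np.r_[np.full(60, -10.0), np.full(40, 10.0)][:, None]
        res = fit_kmeans(X, seed=0)
        assert np.all(res.roi_labels[:60] == 1)
        assert np.all(res.roi_labels[60:] == 2)

    def test_duplicated_rows_leave_centroids_unchanged(self, rng):
        X, _ = _blobs(rng)
        a = fit_kmeans(X, seed=0)
        b = fit_kmeans(np.vstack([X, X]), seed=0)
        np.testing.assert_allclose(
            np.sort(a.centroids, axis=0), np.sort(b.centroids, axis=0), atol=1e-8
        )

    def test_not_enough_distinct_rows(self):
        with pytest.raises(ValueError, match="distinct rows"):
            fit_kmeans(np.ones((10, 3)))

    def test_memberships_are_hard(self, rng):
        X, _ = _blobs(rng)
        res = fit_kmeans(X, seed=0)
        assert set(np.unique(res.memberships)) <= {0.0, 1.0}
        np.testing.assert_array_equal(res.memberships.sum(axis=1), 1.0)


class TestFuzzyCMeans:
    def test_equidistant_point_has_half_memberships(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0], [0.0]])
        res = fit_fcm(X, seed=0, restarts=5)
        np.testing.assert_allclose(res.memberships[-1], [0.5, 0.5], atol=1e-4)

    def test_point_on_centroid_gets_full_membership(self, rng):
        X, _ = _blobs(rng, n1=50, n2=50)
        res = fit_fcm(X, seed=0)
        probe = res.centroids[0][None, :]
        np.testing.assert_allclose(
            res.predict_membership(probe)[0], [1.0, 0.0], atol=1e-12
        )

    def test_hard_labels_match_kmeans_on_separated_blobs(self, rng):
        X, truth = _blobs(rng)
        km = fit_kmeans(X, seed=0)
        fcm = fit_fcm(X, seed=0)
        np.testing.assert_array_equal(km.roi_labels, fcm.roi_labels)
        assert adjusted_rand_score(truth, fcm.roi_labels) == 1.0

    def test_memberships_rows_sum_to_one(self, rng):
        X, _ = _blobs(rng, sep=2.0)
        res = fit_fcm(X, seed=0)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(
            res.roi_labels, np.where(res.memberships[:, 0] >= 0.5, 1, 2)
        )


class TestGmm:
    def test_parameter_recovery_on_separated_mixture(self, rng):
        n1, n2 = 360, 240
        mu2 = np.full(3, 6.0 / np.sqrt(3))
        X = np.vstack(
            [rng.normal(0, 1, size=(n1, 3)), mu2 + rng.normal(0, 1, size=(n2, 3))]
        )
        res = fit_gmm(X, seed=0)
        np.testing.assert_allclose(res.centroids[0], np.zeros(3), atol=0.2)
        np.testing.assert_allclose(res.centroids[1], mu2, atol=0.2)

    def test_posteriors_sum_to_one_and_argmax_labels(self, rng):
        X, _ = _blobs(rng, sep=3.0)
        res = fit_gmm(X, seed=0)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(
            res.roi_labels, np.where(res.memberships.argmax(axis=1) == 0, 1, 2)
        )

    def test_reproducible_under_fixed_seed(self, rng):
        X, _ = _blobs(rng, sep=1.5)
        a = fit_gmm(X, seed=3)
        b = fit_gmm(X, seed=3)
        np.testing.assert_array_equal(a.roi_labels, b.roi_labels)


class TestCanonicalLabeling:
    @pytest.mark.parametrize("fitter", [fit_kmeans, fit_fcm, fit_gmm])
    def test_cluster_one_is_larger(self, fitter, rng):
        X, _ = _blobs(rng, n1=30, n2=70)
        res = fitter(X, seed=0)
        n1 = (res.roi_labels == 1).sum()
        assert n1 >= (res.roi_labels == 2).sum()

    def test_tie_breaks_to_smaller_centroid_norm(self, rng):
        X = np.r_[np.full(10, -1.0), np.full(10, 5.0)][:, None]
        X = X + rng.normal(0, 0.01, size=X.shape)
        res = fit_kmeans(X, seed=0)
        assert abs(res.centroids[0, 0]) < abs(res.centroids[1, 0])


class TestMajorityVote:
    def test_majority_wins(self):
        out = assign_majority(["p"] * 3, np.array([1, 1, 2]))
        assert out[0].cluster == 1
        assert out[0].weight == pytest.approx(2 / 3)

    def test_exact_tie_unassigned(self):
        out = assign_majority(["p", "p"], np.array([1, 2]))
        assert out[0].cluster is None

    def test_unanimous(self):
        out = assign_majority(["p"] * 7, np.array([2] * 7))
        assert out[0].cluster == 2 and out[0].weight == 1.0


class TestFeatureAverage:
    def test_single_roi_patient_keeps_its_label(self, rng):
        X, _ = _blobs(rng)
        res = fit_kmeans(X, seed=0)
        out = assign_feature_average(["p"], X[:1], res)
        assert out[0].cluster == res.roi_labels[0]

    def test_identical_rois_keep_label(self, rng):
        X, _ = _blobs(rng)
        res = fit_kmeans(X, seed=0)
        out = assign_feature_average(["p"] * 3, np.tile(X[0], (3, 1)), res)
        assert out[0].cluster == res.roi_labels[0]

    def test_tied_patient_resolved_toward_nearer_centroid(self, rng):
        """A 6-6 split patient whose averaged vector lies nearer the
        Cluster 1 centroid is assigned to Cluster 1."""
        X, _ = _blobs(rng)
        res = fit_kmeans(X, seed=0)
        rois = np.vstack([np.tile(X[0], (6, 1)), np.tile(X[-1], (6, 1))])
        labels = res.predict_label(rois)
        assert (labels == 1).sum() == 6  # genuine tie under majority vote
        majority = assign_majority(["p"] * 12, labels)
        assert majority[0].cluster is None
        # nudge the average toward centroid 1 by weighting the mean input
        mean_vec = rois.mean(axis=0)
        d = np.linalg.norm(res.centroids - mean_vec, axis=1)
        out = assign_feature_average(["p"] * 12, rois, res)
        assert out[0].cluster == int(np.argmin(d)) + 1
        assert out[0].cluster is not None

    def test_every_patient_assigned(self, rng):
        X, _ = _blobs(rng)
        res = fit_gmm(X, seed=0)
        ids = rng.integers(0, 10, size=X.shape[0])
        out = assign_feature_average(ids, X, res)
        assert all(a.cluster in (1, 2) for a in out)
        assert len(out) == len(set(ids.tolist()))
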