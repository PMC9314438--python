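"""Two-cluster models on normalized ROI features and patient aggregation.

Three unsupervised models are supported: K-means (hard), Fuzzy C-means
(soft memberships), and a Gaussian mixture model with full covariance
(posterior responsibilities). After fitting, clusters are relabeled so
that "Cluster 1" is the larger cluster by ROI count (tie broken toward
the centroid with the smaller norm) -- the survivor-enriched cluster in
the motivating cohort is consistently the majority one.

ROI labels are collapsed to patient level by two rules: *majority vote*
(strict majority of hard labels; an exact tie leaves the patient
unassigned) and *feature averaging* (the patient's ROI vectors are
averaged in normalized space and the averaged vector is assigned by the
fitted model, so every patient receives a cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

MODEL_KINDS = ("kmeans", "fcm", "gmm")
AGGREGATION_METHODS = ("majority_vote", "feature_average")


@dataclass
class ClusterModelResult:
    """A fitted two-cluster model in canonical label order.

    ``roi_labels`` are 1/2 with Cluster 1 the larger cluster;
    ``memberships[:, 0]`` is the weight of Cluster 1. ``centroids`` are
    the cluster centers (component means for the GMM) in the same order.
    """

    model_kind: str
    roi_labels: np.ndarray
    memberships: np.ndarray
    centroids: np.ndarray
    seed: int | None
    hyperparameters: dict
    converged: bool = True
    _gmm: GaussianMixture | None = field(default=None, repr=False)
    _perm: np.ndarray | None = field(default=None, repr=False)

    def predict_membership(self, X: np.ndarray) -> np.ndarray:
        """Membership weights of new vectors, columns = (Cluster 1, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centroids.shape[1]:
            raise ValueError(
                f"expected {self.centroids.shape[1]} features, got {X.shape[1]}"
            )
        if self.model_kind == "kmeans":
            d = cdist(X, self.centroids)
            onehot = np.zeros((X.shape[0], 2))
            onehot[np.arange(X.shape[0]), d.argmin(axis=1)] = 1.0
            return onehot
        if self.model_kind == "fcm":
            return _fcm_memberships(
                X, self.centroids, self.hyperparameters["fuzzifier"]
            )
        if self.model_kind == "gmm":
            return self._gmm.predict_proba(X)[:, self._perm]
        raise ValueError(f"unknown model kind {self.model_kind!r}")

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """Hard 1/2 labels of new vectors (ties favor Cluster 1)."""
        m = self.predict_membership(X)
        return np.where(m[:, 0] >= m[:, 1], 1, 2)


@dataclass
class PatientAssignment:
    """Patient-level cluster from one aggregation rule.

    ``cluster`` is 1, 2 or ``None`` (majority-vote exact tie only);
    ``weight`` is the winning vote fraction or membership weight.
    """

    patient_id: object
    method: str
    cluster: int | None
    weight: float


def _canonicalize(
    kind: str,
    labels0: np.ndarray,
    memberships0: np.ndarray,
    centroids0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reorder raw 0/1 cluster indices so index 0 is 'Cluster 1'."""
    counts = np.bincount(labels0, minlength=2)
    if counts[0] != counts[1]:
        first = int(np.argmax(counts))
    else:
        norms = np.linalg.norm(centroids0, axis=1)
        first = int(np.argmin(norms))
    perm = np.array([first, 1 - first])
    labels = np.where(labels0 == first, 1, 2)
    return labels, memberships0[:, perm], centroids0[perm], perm


def _check_rows(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows = ROIs)")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct rows")
    return X


def fit_kmeans(
    X: np.ndarray, k: int = 2, seed: int | None = 0, restarts: int = 20
) -> ClusterModelResult:
    """Lloyd's algorithm with k-means++ starts, best of ``restarts``."""
    X = _check_rows(X, k)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    onehot = np.zeros((X.shape[0], k))
    onehot[np.arange(X.shape[0]), km.labels_] = 1.0
    labels, members, centroids, _ = _canonicalize(
        "kmeans", km.labels_, onehot, km.cluster_centers_
    )
    return ClusterModelResult(
        model_kind="kmeans",
        roi_labels=labels,
        memberships=members,
        centroids=centroids,
        seed=seed,
        hyperparameters={"k": k, "restarts": restarts},
    )


def _fcm_memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d = cdist(X, centroids)
    u = np.zeros_like(d)
    zero = d <= 1e-300
    any_zero = zero.any(axis=1)
    # singularity rule: a point sitting on a centroid belongs to it fully
    if any_zero.any():
        rows = np.where(any_zero)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        power = 2.0 / (m - 1.0)
        ratio = d[rest][:, :, None] / d[rest][:, None, :]
        u[rest] = 1.0 / np.sum(ratio**power, axis=2)
    return u


def fit_fcm(
    X: np.ndarray,
    k: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = 0,
    restarts: int = 20,
) -> ClusterModelResult:
    """Fuzzy C-means by alternating membership/centroid updates.

    Standard Bezdek iteration: ``u_ic`` proportional to
    ``1 / sum_c' (d_ic / d_ic')^(2/(m-1))`` and centroids the
    ``u^m``-weighted means, run to centroid-shift < ``tol`` from
    ``restarts`` random initializations, keeping the lowest objective
    ``sum u^m d^2``. Non-convergence raises a warning and returns the
    best iterate.
    """
    X = _check_rows(X, k)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        idx = rng.choice(X.shape[0], size=k, replace=False)
        centroids = X[idx].copy()
        converged = False
        for _ in range(max_iter):
            u = _fcm_memberships(X, centroids, fuzzifier)
            um = u**fuzzifier
            new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
            centroids = new_centroids
            if shift < tol:
                converged = True
                break
        u = _fcm_memberships(X, centroids, fuzzifier)
        objective = float(np.sum(u**fuzzifier * cdist(X, centroids) ** 2))
        if best is None or objective < best[0]:
            best = (objective, u, centroids, converged)
    _, u, centroids, converged = best
    if not converged:
        warnings.warn("fuzzy C-means did not converge; returning best iterate")
    labels0 = u.argmax(axis=1)
    labels, members, centroids, _ = _canonicalize("fcm", labels0, u, centroids)
    return ClusterModelResult(
        model_kind="fcm",
        roi_labels=labels,
        memberships=members,
        centroids=centroids,
        seed=seed,
        hyperparameters={
            "k": k,
            "fuzzifier": fuzzifier,
            "tol": tol,
            "max_iter": max_iter,
            "restarts": restarts,
        },
        converged=converged,
    )


def fit_gmm(
    X: np.ndarray,
    k: int = 2,
    reg: float = 1e-6,
    tol: float = 1e-6,
    seed: int | None = 0,
    restarts: int = 20,
) -> ClusterModelResult:
    """Full-covariance Gaussian mixture by EM, best of ``restarts``."""
    X = _check_rows(X, k)
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=reg,
        tol=tol,
        n_init=restarts,
        random_state=seed,
    ).fit(X)
    resp = gmm.predict_proba(X)
    labels0 = resp.argmax(axis=1)
    labels, members, centroids, perm = _canonicalize(
        "gmm", labels0, resp, gmm.means_
    )
    return ClusterModelResult(
        model_kind="gmm",
        roi_labels=labels,
        memberships=members,
        centroids=centroids,
        seed=seed,
        hyperparameters={"k": k, "reg": reg, "tol": tol, "restarts": restarts},
        converged=bool(gmm.converged_),
        _gmm=gmm,
        _perm=perm,
    )


MODEL_FITTERS = {"kmeans": fit_kmeans, "fcm": fit_fcm, "gmm": fit_gmm}


def assign_majority(
    patient_ids: Sequence, roi_labels: np.ndarray
) -> list[PatientAssignment]:
    """Strict-majority patient assignment; exact ties stay unassigned."""
    df = pd.DataFrame({"patient_id": list(patient_ids), "label": roi_labels})
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        n1 = int((grp["label"] == 1).sum())
        n2 = int((grp["label"] == 2).sum())
        if n1 > n2:
            out.append(PatientAssignment(pid, "majority_vote", 1, n1 / (n1 + n2)))
        elif n2 > n1:
            out.append(PatientAssignment(pid, "majority_vote", 2, n2 / (n1 + n2)))
        else:
            out.append(PatientAssignment(pid, "majority_vote", None, 0.5))
    return out


def assign_feature_average(
    patient_ids: Sequence,
    normalized_vectors: np.ndarray,
    model: ClusterModelResult,
) -> list[PatientAssignment]:
    """Average each patient's normalized vectors; assign by the model.

    The averaged patient-representing vector is fed back through the
    fitted model (nearest centroid / fuzzy membership / posterior), so
    every patient receives a cluster -- including majority-vote ties.
    """
    X = np.asarray(normalized_vectors, dtype=float)
    df = pd.DataFrame({"patient_id": list(patient_ids)})
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        mean_vec = X[grp.index.to_numpy()].mean(axis=0, keepdims=True)
        m = model.predict_membership(mean_vec)[0]
        cluster = 1 if m[0] >= m[1] else 2
        out.append(
            PatientAssignment(pid, "feature_average", cluster, float(m[cluster - 1]))
        )
    return out
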