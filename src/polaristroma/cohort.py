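"""Synthetic ROI-feature cohorts with planted cluster and survival structure.

Emulates the study design that motivates the pipeline: a few dozen
patients, each contributing a handful of stromal ROIs, where ROIs fall
into one of two morphological phenotypes and 5-year survival probability
differs by phenotype.

Features are generated log-normally: each ROI's 18 raw features are
``exp`` of Gaussian draws around its phenotype's log-space mean vector.
This matches the pipeline's normalization model (a log transform is
expected to Gaussianize the skewed raw features). The second column, a
correlation-analogue, is shifted to straddle zero so the normalizer's
shifted-log branch is exercised. Cluster separation is parameterized as
the per-feature standardized mean difference in log space, with
alternating sign across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FEATURES = 18
#: Raw-space offset subtracted from feature f02 so it can go negative.
CORRELATION_COLUMN_SHIFT = 1.5
_CORRELATION_COLUMN = 1


def default_cluster_means(
    separation: float = 4.0, cluster_sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Two log-space mean vectors whose per-feature standardized
    difference is ``separation``, signs alternating across features."""
    mean1 = np.zeros(N_FEATURES)
    signs = np.where(np.arange(N_FEATURES) % 2 == 0, 1.0, -1.0)
    # the zero-noise degenerate limit keeps distinct means (unit scale)
    scale = cluster_sd if cluster_sd > 0 else 1.0
    mean2 = mean1 + signs * separation * scale
    return mean1, mean2


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the motivating study: 32 patients, 3-14 ROIs each
    (~300 ROIs total), roughly 72% of patients in the survivor-enriched
    phenotype, 5-year survival probabilities (0.9, 0.3) by phenotype,
    and 10% within-patient phenotype mixing. ``cluster_means`` and
    ``cluster_sd`` live in log-feature space (see module docstring).
    """

    n_patients: int = 32
    rois_per_patient_range: tuple[int, int] = (3, 14)
    n_features: int = N_FEATURES
    cluster_means: tuple[np.ndarray, np.ndarray] | None = None
    cluster_sd: float | np.ndarray = 1.0
    separation: float = 4.0
    cluster1_fraction: float = 0.72
    within_patient_mixing: float = 0.1
    survival_prob_by_class: tuple[float, float] = (0.9, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        lo, hi = self.rois_per_patient_range
        if lo < 1 or hi < lo:
            raise ValueError("rois_per_patient_range must satisfy 1 <= min <= max")
        if self.n_features != N_FEATURES:
            raise ValueError(f"n_features is fixed at {N_FEATURES}")
        for p in (
            self.cluster1_fraction,
            self.within_patient_mixing,
            *self.survival_prob_by_class,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.asarray(self.cluster_sd) < 0):
            raise ValueError("cluster_sd must be nonnegative")
        if self.cluster_means is None:
            sd = float(np.max(np.atleast_1d(self.cluster_sd)))
            self.cluster_means = default_cluster_means(self.separation, sd)
        m1, m2 = (np.asarray(m, dtype=float) for m in self.cluster_means)
        if m1.shape != (N_FEATURES,) or m2.shape != (N_FEATURES,):
            raise ValueError("cluster mean vectors must have length 18")
        self.cluster_means = (m1, m2)


def raw_class_means(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw-space feature vectors a zero-noise ROI of each class takes."""
    out = []
    for m in spec.cluster_means:
        raw = np.exp(m)
        raw = raw.copy()
        raw[_CORRELATION_COLUMN] -= CORRELATION_COLUMN_SHIFT
        out.append(raw)
    return tuple(out)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: one row per ROI.

    Columns: ``patient_id``, ``roi_id``, ``f01``..``f18``,
    ``latent_class_patient``, ``latent_class_roi``, ``survived``.
    Survival is constant within a patient and depends on the patient's
    latent class; an ROI's class flips from its patient's with
    probability ``within_patient_mixing``.
    """
    rng = np.random.default_rng(spec.seed)
    m1, m2 = spec.cluster_means
    sd = np.broadcast_to(np.asarray(spec.cluster_sd, dtype=float), (N_FEATURES,))
    lo, hi = spec.rois_per_patient_range

    rows = []
    for p in range(1, spec.n_patients + 1):
        patient_class = 1 if rng.random() < spec.cluster1_fraction else 2
        p_survive = spec.survival_prob_by_class[patient_class - 1]
        survived = int(rng.random() < p_survive)
        n_rois = int(rng.integers(lo, hi + 1))
        for r in range(1, n_rois + 1):
            roi_class = patient_class
            if rng.random() < spec.within_patient_mixing:
                roi_class = 3 - roi_class
            mean = m1 if roi_class == 1 else m2
            log_features = mean + sd * rng.standard_normal(N_FEATURES)
            raw = np.exp(log_features)
            raw[_CORRELATION_COLUMN] -= CORRELATION_COLUMN_SHIFT
            row = {
                "patient_id": p,
                "roi_id": r,
                **{f"f{k + 1:02d}": raw[k] for k in range(N_FEATURES)},
                "latent_class_patient": patient_class,
                "latent_class_roi": roi_class,
                "survived": survived,
            }
            rows.append(row)
    return pd.DataFrame(rows)


#: Column names of the 18 features in a generated cohort CSV.
COHORT_FEATURE_COLUMNS = tuple(f"f{k + 1:02d}" for k in range(N_FEATURES))
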