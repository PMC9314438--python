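"""The 18-feature ROI vector and the two-step normalization.

Each ROI contributes three polarimetric summaries -- the median MIR
(intensity), the median MAD over valid pixels (alignment, degrees) and
the abundance ratio (fraction of pixels with R^2 above threshold) -- plus
the five Haralick texture features of each of the three parametric
images, 18 features in total.

Before clustering, every feature column undergoes a logarithmic
transformation followed by Z-score normalization. Columns that can reach
zero or negative values (the GLCM correlation analogues) are shifted so
their minimum maps to 1 before the log; the fitted shift, mean and SD are
stored so patient-averaged vectors can be projected into the same space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .polarimetry import (
    AbundanceImage,
    AlignmentImage,
    IntensityImage,
    PolarimetricStack,
    abundance_image,
    alignment_image,
    intensity_image,
    orientation_image,
)
from .texture import FEATURE_ORDER, roi_texture

POLARIMETRIC_FEATURES = ("median_intensity", "median_alignment", "abundance_ratio")
PARAMETRIC_IMAGE_NAMES = ("intensity", "alignment", "abundance")
TEXTURE_FEATURES = tuple(
    f"{img}_{feat}" for img in PARAMETRIC_IMAGE_NAMES for feat in FEATURE_ORDER
)
#: Canonical order of the 18 features of one ROI.
FEATURE_NAMES = POLARIMETRIC_FEATURES + TEXTURE_FEATURES


class RoiRect(NamedTuple):
    """Rectangular ROI, 0-based half-open pixel intervals."""

    x: int
    y: int
    width: int
    height: int


@dataclass
class ParametricImages:
    """The three derived maps of one field of view."""

    intensity: IntensityImage
    alignment: AlignmentImage
    abundance: AbundanceImage


def derive_parametric(
    stack: PolarimetricStack,
    window: int = 5,
    threshold: float = 0.75,
) -> ParametricImages:
    """Derive intensity, alignment and abundance images from a stack."""
    orient = orientation_image(stack)
    return ParametricImages(
        intensity=intensity_image(stack),
        alignment=alignment_image(orient, window=window),
        abundance=abundance_image(stack, threshold=threshold),
    )


def summarize_roi(
    images: ParametricImages, roi: RoiRect
) -> tuple[float, float, float]:
    """Median MIR, median MAD (valid pixels only) and abundance ratio."""
    x, y, w, h = roi
    mir = images.intensity.mir
    if x < 0 or y < 0 or x + w > mir.shape[1] or y + h > mir.shape[0]:
        raise ValueError("ROI outside image")
    mir_patch = mir[y : y + h, x : x + w]
    mad_patch = images.alignment.mad[y : y + h, x : x + w]
    mad_valid = images.alignment.valid_mask[y : y + h, x : x + w]
    if not mad_valid.any():
        raise ValueError("ROI contains no valid alignment pixels")
    mask_patch = images.abundance.mask[y : y + h, x : x + w]
    return (
        float(np.median(mir_patch)),
        float(np.median(mad_patch[mad_valid])),
        float(mask_patch.mean()),
    )


def compute_roi_features(images: ParametricImages, roi: RoiRect) -> dict[str, float]:
    """All 18 named features of one ROI."""
    med_mir, med_mad, abundance = summarize_roi(images, roi)
    out = {
        "median_intensity": med_mir,
        "median_alignment": med_mad,
        "abundance_ratio": abundance,
    }
    planes = {
        "intensity": (images.intensity.mir, None),
        "alignment": (images.alignment.mad, images.alignment.valid_mask),
        "abundance": (images.abundance.r2, None),
    }
    for name, (plane, valid) in planes.items():
        tex = roi_texture(plane, roi, valid_mask=valid)
        for feat in FEATURE_ORDER:
            out[f"{name}_{feat}"] = getattr(tex, feat)
    return out


def assemble(records: list[dict]) -> pd.DataFrame:
    """Build the tidy cohort table keyed by (patient_id, roi_id).

    Each record must carry ``patient_id``, ``roi_id``, ``survived`` and
    all 18 features; survival must be constant within a patient.
    """
    required = {"patient_id", "roi_id", "survived", *FEATURE_NAMES}
    for rec in records:
        missing = required - rec.keys()
        if missing:
            raise ValueError(
                f"ROI {rec.get('patient_id')}/{rec.get('roi_id')} is missing "
                f"fields: {sorted(missing)}"
            )
    df = pd.DataFrame.from_records(records)
    cols = ["patient_id", "roi_id", *FEATURE_NAMES, "survived"]
    extra = [c for c in df.columns if c not in cols]
    df = df[cols + extra]
    per_patient = df.groupby("patient_id")["survived"].nunique()
    bad = per_patient[per_patient > 1]
    if not bad.empty:
        raise ValueError(
            f"survival label not constant within patient(s): {list(bad.index)}"
        )
    return df


@dataclass
class NormalizationModel:
    """Fitted parameters of the log + Z-score transform."""

    feature_names: tuple[str, ...]
    shifts: np.ndarray
    means: np.ndarray
    sds: np.ndarray


def fit_normalizer(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> NormalizationModel:
    """Fit the two-step normalization on the ROI rows of a cohort table.

    Per feature: shift ``s = 1 - min(x)`` if the minimum is nonpositive
    (else 0), then ``u = log(x + s)``, then store the mean and SD of u.
    A constant column cannot be Z-scored and raises, naming the feature.
    """
    X = table[list(feature_names)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the normalizer")
    mins = X.min(axis=0)
    constant = X.max(axis=0) == mins
    if np.any(constant):
        name = feature_names[int(np.argmax(constant))]
        raise ValueError(f"feature '{name}' is constant; cannot Z-score")
    shifts = np.where(mins <= 0, 1.0 - mins, 0.0)
    u = np.log(X + shifts)
    means = u.mean(axis=0)
    sds = u.std(axis=0)
    return NormalizationModel(
        feature_names=tuple(feature_names), shifts=shifts, means=means, sds=sds
    )


def apply_normalizer(
    model: NormalizationModel, vectors: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Project vectors into the fitted normalized space."""
    if isinstance(vectors, pd.DataFrame):
        X = vectors[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
    shifted = X + model.shifts
    if np.any(shifted <= 0):
        col = int(np.argwhere(shifted <= 0)[0, 1])
        raise ValueError(
            f"feature '{model.feature_names[col]}' out of the log transform "
            "domain (x + shift <= 0)"
        )
    return (np.log(shifted) - model.means) / model.sds


def normalize_table(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> tuple[np.ndarray, NormalizationModel]:
    """Fit on the table's ROI rows and return the normalized matrix."""
    model = fit_normalizer(table, feature_names)
    return apply_normalizer(model, table), model
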