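"""Gray-level co-occurrence texture features of parametric-image ROIs.

Each ROI patch is min-max quantized to 8 gray levels, co-occurrence
matrices are built at distance 1 for the four standard directions
(0, 45, 90, 135 degrees; symmetric, normalized), and the five Haralick
features -- contrast, correlation, energy, homogeneity, entropy -- are
computed per direction and averaged into direction-independent metrics.

Pair counting is delegated to :func:`skimage.feature.graycomatrix`; the
feature formulas are implemented here because the set includes entropy
(absent from ``graycoprops``) and a defined-zero rule for the correlation
of a zero-variance matrix. Entropy is in bits (log base 2) with the
``0 log 0 = 0`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

N_GRAY_LEVELS = 8
DIRECTIONS_DEG = (0, 45, 90, 135)

FEATURE_ORDER = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass(frozen=True)
class TextureFeatureSet:
    """The five Haralick features, averaged over the four directions."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_ORDER])


def quantize(patch: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Bin a real-valued patch into integer gray levels ``1..levels``.

    Equal-width bins span the patch's own [min, max]; a constant patch
    maps entirely to level 1. Quantization is therefore invariant to any
    affine rescaling of the patch.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    lo, hi = patch.min(), patch.max()
    if hi == lo:
        return np.ones(patch.shape, dtype=np.uint8)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(np.int64) + 1
    return np.clip(q, 1, levels).astype(np.uint8)


def glcm(
    quantized: np.ndarray, direction: float, distance: int = 1
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset.

    ``direction`` is one of 0, 45, 90, 135 degrees; rows/columns index
    gray levels 1..8 (stored 0-based). Raises if the image admits no
    pixel pair at that offset.
    """
    quantized = np.asarray(quantized)
    if quantized.min() < 1 or quantized.max() > N_GRAY_LEVELS:
        raise ValueError("quantized values must lie in 1..8")
    if direction not in DIRECTIONS_DEG:
        raise ValueError(f"direction must be one of {DIRECTIONS_DEG}")
    # skimage's angle maps to offset (sin, cos) in (row, col); negating
    # puts 45 on the up-right anti-diagonal (Haralick's convention).
    counts = graycomatrix(
        (quantized - 1).astype(np.uint8),
        distances=[distance],
        angles=[-np.deg2rad(direction)],
        levels=N_GRAY_LEVELS,
        symmetric=True,
        normed=False,
    )[:, :, 0, 0].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for this offset")
    return counts / total


def haralick(p: np.ndarray) -> dict[str, float]:
    """The five Haralick features of one normalized GLCM.

    contrast    = sum p(i,j) (i-j)^2
    correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j), 0 when
                  either marginal variance vanishes
    energy      = sum p^2
    homogeneity = sum p / (1 + |i-j|)
    entropy     = -sum p log2 p   (0 log 0 := 0)
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (N_GRAY_LEVELS, N_GRAY_LEVELS):
        raise ValueError("GLCM must be 8x8")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized (nonnegative, sum 1)")

    levels = np.arange(1, N_GRAY_LEVELS + 1, dtype=float)
    i = levels[:, None]
    j = levels[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(levels @ pi)
    mu_j = float(levels @ pj)
    var_i = float(((levels - mu_i) ** 2) @ pi)
    var_j = float(((levels - mu_j) ** 2) @ pj)

    contrast = float(np.sum(p * (i - j) ** 2))
    if var_i > 0 and var_j > 0:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = 0.0
    energy = float(np.sum(p * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def patch_texture(patch: np.ndarray, distance: int = 1) -> TextureFeatureSet:
    """Quantize a patch and average the five features over 4 directions."""
    q = quantize(patch)
    per_direction = [haralick(glcm(q, d, distance)) for d in DIRECTIONS_DEG]
    means = {
        k: float(np.mean([f[k] for f in per_direction])) for k in FEATURE_ORDER
    }
    return TextureFeatureSet(**means)


def roi_texture(
    image: np.ndarray,
    roi,
    valid_mask: np.ndarray | None = None,
    distance: int = 1,
) -> TextureFeatureSet:
    """Texture features of a rectangular ROI of a parametric image.

    ``roi`` is ``(x, y, width, height)``, 0-based and half-open. When a
    validity mask is given (alignment images have an invalid border), the
    patch is cropped to the bounding box of its valid pixels first.
    """
    x, y, w, h = roi
    image = np.asarray(image, dtype=float)
    if x < 0 or y < 0 or x + w > image.shape[1] or y + h > image.shape[0]:
        raise ValueError("ROI outside image")
    patch = image[y : y + h, x : x + w]
    if valid_mask is not None:
        sub = valid_mask[y : y + h, x : x + w]
        rows = np.flatnonzero(sub.any(axis=1))
        cols = np.flatnonzero(sub.any(axis=0))
        if rows.size == 0:
            raise ValueError("ROI contains no valid pixels")
        patch = patch[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return patch_texture(patch, distance)
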