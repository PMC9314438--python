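"""Parametric images from rotating crossed-polarizer stacks.

Birefringent structures (collagen fibers) between crossed linear polarizers
transmit light with a sin^2(2(theta - phi)) dependence on the polarizer
rotation angle theta, where phi is the in-plane fiber orientation; the
signal is 90-degree periodic. From an 18-frame stack acquired at 5-degree
steps this module derives three geometry-independent maps:

* **intensity** (MIR) -- per-pixel sample standard deviation of brightness
  across the angular sweep; large where strongly birefringent material
  modulates the signal, zero where nothing modulates.
* **alignment** (MAD) -- mean pairwise wrapped angular difference of the
  peak-signal angles inside a sliding window; low values mean locally
  aligned fibers, high values mean disorganized orientation.
* **abundance** (R^2) -- goodness of fit of the per-pixel angular
  modulation to the sinusoid-squared model, an amplitude-independent
  detector of birefringent material; thresholded at R^2 > 0.75.

All angles are degrees. Orientations are equivalence classes modulo 90
(the crossed-polarizer period), so angular differences wrap at 45.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical acquisition angles: 0, 5, ..., 85 degrees.
ACQUISITION_ANGLES = np.arange(0.0, 90.0, 5.0)

#: Default R^2 threshold separating collagenous stroma from background.
DEFAULT_R2_THRESHOLD = 0.75

#: Default sliding-window side for the alignment image (5 px ~ 4 um at
#: 0.8 um/px).
DEFAULT_MAD_WINDOW = 5


@dataclass
class PolarimetricStack:
    """Co-registered crossed-polarizer frames with their rotation angles.

    Parameters
    ----------
    frames
        Array of shape ``(Z, H, W)`` with nonnegative pixel brightness.
    angles
        Strictly increasing polarizer angles in degrees, uniform step.
    pixel_size
        Lateral pixel size in micrometers.
    """

    frames: np.ndarray
    angles: np.ndarray = field(default_factory=lambda: ACQUISITION_ANGLES.copy())
    pixel_size: float = 0.8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (Z, H, W)")
        z, h, w = self.frames.shape
        if h == 0 or w == 0:
            raise ValueError("zero-area image")
        if z != self.angles.size:
            raise ValueError(
                f"{z} frames but {self.angles.size} angles"
            )
        steps = np.diff(self.angles)
        if self.angles.size > 1 and not (
            np.all(steps > 0) and np.allclose(steps, steps[0])
        ):
            raise ValueError("angles must be strictly increasing with uniform step")
        if np.any(self.frames < 0):
            raise ValueError("frames must be nonnegative")

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class IntensityImage:
    """Per-pixel MIR map (sample SD of brightness across angles)."""

    mir: np.ndarray


@dataclass(frozen=True)
class OrientationImage:
    """Per-pixel angle of maximum transmitted signal, degrees in [0, 90)."""

    b: np.ndarray


@dataclass(frozen=True)
class AlignmentImage:
    """Per-pixel MAD map in degrees [0, 45]; NaN where the window exits."""

    mad: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class AbundanceImage:
    """Per-pixel sinusoid-squared goodness of fit and its threshold mask."""

    r2: np.ndarray
    mask: np.ndarray
    threshold: float = DEFAULT_R2_THRESHOLD


def flood_field_correct(
    stack: PolarimetricStack,
    reference: PolarimetricStack,
    floor: float = 0.0,
) -> PolarimetricStack:
    """Divide out illumination inhomogeneity using a no-sample reference.

    Each frame is divided pixel-wise by its reference frame normalized to
    unit mean, so overall brightness scale is preserved while spatial gain
    structure is removed.

    Raises
    ------
    ValueError
        If shapes or angles disagree, or if any reference pixel is at or
        below ``floor`` (reported with the offending pixel count).
    """
    if stack.frames.shape != reference.frames.shape:
        raise ValueError("reference shape does not match stack")
    if not np.array_equal(stack.angles, reference.angles):
        raise ValueError("reference angles do not match stack")
    bad = int(np.count_nonzero(reference.frames <= floor))
    if bad:
        raise ValueError(
            f"reference has {bad} pixel(s) <= {floor}; cannot flood-field correct"
        )
    gain = reference.frames / reference.frames.mean(axis=(1, 2), keepdims=True)
    return PolarimetricStack(
        frames=stack.frames / gain,
        angles=stack.angles.copy(),
        pixel_size=stack.pixel_size,
    )


def intensity_image(stack: PolarimetricStack) -> IntensityImage:
    """Per-pixel sample standard deviation across the Z frames (ddof=1)."""
    if stack.n_angles < 2:
        raise ValueError("intensity image needs at least 2 frames")
    return IntensityImage(mir=np.std(stack.frames, axis=0, ddof=1))


def orientation_image(stack: PolarimetricStack) -> OrientationImage:
    """Angle of the frame-wise maximum at each pixel; ties take the
    smallest angle (``argmax`` returns the first maximum)."""
    idx = np.argmax(stack.frames, axis=0)
    return OrientationImage(b=stack.angles[idx] % 90.0)


def wrapped_angle_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute difference of orientations modulo 90 degrees, in [0, 45]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 90.0
    return np.minimum(d, 90.0 - d)


def alignment_image(
    orient: OrientationImage, window: int = DEFAULT_MAD_WINDOW
) -> AlignmentImage:
    """Mean pairwise wrapped angular difference over a sliding window.

    For every pixel whose ``window x window`` neighborhood lies fully
    inside the image, averages ``d(a, b) = min(|a-b|, 90-|a-b|)`` over all
    n(n-1)/2 unordered pixel pairs of the neighborhood. Border pixels get
    NaN and ``valid_mask`` False.
    """
    b = np.asarray(orient.b, dtype=float)
    h, w = b.shape
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(h, w):
        raise ValueError("window larger than image")

    vh, vw = h - window + 1, w - window + 1
    offsets = [(i, j) for i in range(window) for j in range(window)]
    views = [b[i : i + vh, j : j + vw] for i, j in offsets]
    acc = np.zeros((vh, vw))
    n = len(offsets)
    for p in range(n):
        for q in range(p + 1, n):
            acc += wrapped_angle_difference(views[p], views[q])
    acc /= n * (n - 1) / 2.0

    mad = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    r = window // 2
    mad[r : r + vh, r : r + vw] = acc
    valid[r : r + vh, r : r + vw] = True
    return AlignmentImage(mad=mad, valid_mask=valid)


def _harmonic_design(angles_deg: np.ndarray) -> np.ndarray:
    t = np.radians(angles_deg)
    return np.column_stack([np.ones_like(t), np.cos(4 * t), np.sin(4 * t)])


def abundance_image(
    stack: PolarimetricStack, threshold: float = DEFAULT_R2_THRESHOLD
) -> AbundanceImage:
    """Goodness of fit of each pixel's angular modulation to the model.

    The sinusoid-squared family ``A sin^2(2(theta - phi)) + c`` is exactly
    the harmonic family ``a0 + a1 cos(4 theta) + a2 sin(4 theta)``, so the
    fit is solved per pixel by linear least squares in closed form. R^2 is
    clamped to [0, 1] and defined as 0 on pixels with zero modulation
    variance; the mask is ``r2 > threshold``.
    """
    z = stack.n_angles
    if z < 4:
        raise ValueError("abundance image needs at least 4 frames")
    y = stack.frames.reshape(z, -1)
    design = _harmonic_design(stack.angles)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = np.einsum("ij,ij->j", resid, resid)
    centered = y - y.mean(axis=0)
    ss_tot = np.einsum("ij,ij->j", centered, centered)
    r2 = np.zeros(y.shape[1])
    ok = ss_tot > 0
    r2[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    r2 = np.clip(r2, 0.0, 1.0).reshape(stack.shape)
    return AbundanceImage(r2=r2, mask=r2 > threshold, threshold=threshold)
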