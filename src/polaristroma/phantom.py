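"""Ground-truthed synthetic crossed-polarizer stacks of fiber phantoms.

The generator renders anti-aliased straight fiber segments with random
position, orientation and birefringence amplitude on a dark background,
then synthesizes the 18-frame angular sweep from the sinusoid-squared
signal model ``gain * (A sin^2(2(theta - phi)) + offset) + noise``. A
:class:`GroundTruth` sidecar carries per-pixel orientation, amplitude,
fiber mask and the multiplicative gain field so every downstream stage can
be validated without real data.

Fiber orientations are drawn from a von Mises distribution wrapped onto
the 90-degree orientation period: concentration 0 gives fully disordered
phantoms, large concentrations nearly parallel fibers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .polarimetry import ACQUISITION_ANGLES, PolarimetricStack


@dataclass
class PhantomSpec:
    """Parameters of a fiber phantom and its acquisition.

    ``coverage_fraction``, when set, makes the generator keep adding
    fibers until that fraction of pixels is covered, overriding
    ``fiber_count``. All scales are nonnegative; the orientation mean is
    reduced modulo 90 (the crossed-polarizer signal period).
    """

    width: int = 256
    height: int = 256
    pixel_size: float = 0.8
    fiber_count: int = 40
    fiber_orientation_mean: float = 45.0
    fiber_orientation_concentration: float = 0.0
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    dark_offset: float = 0.02
    noise_sd: float = 0.01
    gain_map_sd: float = 0.0
    coverage_fraction: float | None = None
    fiber_width: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("zero-area image")
        self.fiber_orientation_mean = float(self.fiber_orientation_mean) % 90.0
        for name in ("dark_offset", "noise_sd", "gain_map_sd",
                     "fiber_orientation_concentration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("amplitude_range must satisfy 0 <= min <= max")
        if self.coverage_fraction is not None and not (
            0.0 < self.coverage_fraction <= 1.0
        ):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.fiber_width <= 0:
            raise ValueError("fiber_width must be positive")


@dataclass
class GroundTruth:
    """Per-pixel truth for a phantom.

    ``orientation_map`` is NaN on background; ``fiber_mask`` is True
    exactly where ``amplitude_map > 0``.
    """

    orientation_map: np.ndarray
    amplitude_map: np.ndarray
    fiber_mask: np.ndarray
    gain_map: np.ndarray


def _sample_orientation(rng: np.random.Generator, spec: PhantomSpec) -> float:
    # von Mises on the doubled... quadrupled circle: the 90-degree
    # orientation period maps to the full 2*pi circle (deg * pi/45).
    loc = spec.fiber_orientation_mean * math.pi / 45.0
    sample = rng.vonmises(loc, spec.fiber_orientation_concentration)
    return (sample % (2.0 * math.pi)) * 45.0 / math.pi


def _paint_fiber(
    amplitude: np.ndarray,
    orientation: np.ndarray,
    rng: np.random.Generator,
    spec: PhantomSpec,
) -> None:
    h, w = amplitude.shape
    phi = _sample_orientation(rng, spec)
    amp = rng.uniform(*spec.amplitude_range)
    cx = rng.uniform(0, w)
    cy = rng.uniform(0, h)
    length = rng.uniform(0.3, 0.7) * max(h, w)
    # Image-plane direction of the segment; the sign convention only
    # affects spatial layout, the polarimetric phase is phi itself.
    dx = math.cos(math.radians(phi)) * length / 2.0
    dy = -math.sin(math.radians(phi)) * length / 2.0
    x0, y0, x1, y1 = cx - dx, cy - dy, cx + dx, cy + dy

    pad = spec.fiber_width / 2.0 + 1.5
    c0 = max(int(math.floor(min(x0, x1) - pad)), 0)
    c1 = min(int(math.ceil(max(x0, x1) + pad)) + 1, w)
    r0 = max(int(math.floor(min(y0, y1) - pad)), 0)
    r1 = min(int(math.ceil(max(y0, y1) + pad)) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return

    yy, xx = np.mgrid[r0:r1, c0:c1]
    vx, vy = x1 - x0, y1 - y0
    seg_len2 = vx * vx + vy * vy
    t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / seg_len2, 0.0, 1.0)
    dist = np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy))
    coverage = np.clip(spec.fiber_width / 2.0 + 0.5 - dist, 0.0, 1.0)
    contrib = coverage * amp

    patch_a = amplitude[r0:r1, c0:c1]
    patch_o = orientation[r0:r1, c0:c1]
    stronger = contrib > patch_a
    patch_a[stronger] = contrib[stronger]
    patch_o[stronger] = phi


def _gain_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    if spec.gain_map_sd == 0:
        return np.ones((spec.height, spec.width))
    coarse = rng.normal(size=(6, 6))
    field = ndimage.zoom(
        coarse, (spec.height / 6.0, spec.width / 6.0), order=3, mode="nearest"
    )[: spec.height, : spec.width]
    field = (field - field.mean()) / max(field.std(), 1e-12)
    return np.clip(1.0 + spec.gain_map_sd * field, 0.05, None)


def generate_stack(spec: PhantomSpec) -> tuple[PolarimetricStack, GroundTruth]:
    """Render a fiber phantom and synthesize its 18-angle stack.

    Overlapping fibers keep the larger amplitude contribution and the
    orientation of the stronger fiber, so the ground truth stays
    single-valued. Noise is additive Gaussian, independent per frame, and
    frames are clipped at zero (detector nonnegativity).
    """
    rng = np.random.default_rng(spec.seed)
    amplitude = np.zeros((spec.height, spec.width))
    orientation = np.full((spec.height, spec.width), np.nan)

    if spec.coverage_fraction is not None:
        max_fibers = 100_000
        count = 0
        while amplitude.astype(bool).mean() < spec.coverage_fraction:
            _paint_fiber(amplitude, orientation, rng, spec)
            count += 1
            if count >= max_fibers:
                raise RuntimeError(
                    "coverage target not reached after 100000 fibers"
                )
    else:
        for _ in range(spec.fiber_count):
            _paint_fiber(amplitude, orientation, rng, spec)

    gain = _gain_field(rng, spec)
    theta = np.radians(ACQUISITION_ANGLES)
    phi = np.radians(np.where(np.isnan(orientation), 0.0, orientation))
    modulation = np.sin(2.0 * (theta[:, None, None] - phi[None])) ** 2
    signal = amplitude[None] * modulation + spec.dark_offset
    frames = gain[None] * signal
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    stack = PolarimetricStack(
        frames=frames, angles=ACQUISITION_ANGLES.copy(), pixel_size=spec.pixel_size
    )
    truth = GroundTruth(
        orientation_map=orientation,
        amplitude_map=amplitude,
        fiber_mask=amplitude > 0,
        gain_map=gain,
    )
    return stack, truth
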