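import numpy as np
import pytest

from polaristroma.polarimetry import ACQUISITION_ANGLES, PolarimetricStack


def model_signal(phi_deg: float, amplitude: float = 1.0, offset: float = 0.0):
    """The 18-sample sinusoid-squared signal of one pixel."""
    t = np.radians(ACQUISITION_ANGLES)
    return amplitude * np.sin(2.0 * (t - np.radians(phi_deg))) ** 2 + offset


def pixel_stack(values) -> PolarimetricStack:
    """An 18-frame stack consisting of a single pixel."""
    values = np.asarray(values, dtype=float)
    return PolarimetricStack(frames=values.reshape(-1, 1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
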