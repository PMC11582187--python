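import numpy as np
import pytest

from gelstrain import (
    LVPhantomSpec,
    MaxwellMode,
    MaxwellSpectrum,
    default_calibration,
)


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture
def single_mode():
    """Crossover at exactly 1 Hz with modulus 1000 Pa."""
    return MaxwellSpectrum([MaxwellMode(2000.0, 1.0 / (2.0 * np.pi))])


@pytest.fixture
def two_mode():
    return MaxwellSpectrum([MaxwellMode(600.0, 1.0), MaxwellMode(400.0, 0.01)])


@pytest.fixture
def relax_spectrum():
    """The generator pair used throughout the relaxation-fit tests."""
    return MaxwellSpectrum([MaxwellMode(800.0, 10.0), MaxwellMode(200.0, 0.5)])


@pytest.fixture
def infarct_phantom():
    return LVPhantomSpec(infarct_span=90.0, transition_width=0.0, point_noise_sd=0.0)


def circular_boundary_distance(a: int, b: int, n: int = 24) -> int:
    return min((a - b) % n, (b - a) % n)
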