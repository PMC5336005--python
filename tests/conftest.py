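import numpy as np
import pytest

from fingertap import PatternSpec, SensorSpec, generate_session
from fingertap.simulate import quiet_sensor


@pytest.fixture(scope="session")
def clean_pattern1():
    """One noise-free moderate-tapping session, shared across tests."""
    return generate_session(PatternSpec.preset(1), quiet_sensor(), seed=3)


@pytest.fixture(scope="session")
def noisy_pattern1():
    """Pattern 1 with the default sensor-noise model."""
    return generate_session(PatternSpec.preset(1), SensorSpec(), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotations(n: int, seed: int = 0) -> np.ndarray:
    """Uniformly random rotation matrices (scipy backend, fixed seed)."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()
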