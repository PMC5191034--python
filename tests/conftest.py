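import numpy as np
import pytest

from motionfis import mamdani, synthetic
from motionfis.imu_signals import stream_from_arrays


@pytest.fixture(scope="session")
def set1_model():
    return mamdani.build_set1()


@pytest.fixture(scope="session")
def set2_model():
    return mamdani.build_set2()


@pytest.fixture(scope="session")
def worked_vector():
    """The published SET-2 feature vector whose output is the sit index."""
    return {
        "theta_A": 4.76,
        "theta_B": 86.0,
        "gamma_wAx": 5.11,
        "gamma_gBx": 0.000588,
        "sigma_gAx": 0.0114,
    }


@pytest.fixture
def constant_stream():
    """2-s, 20 Hz chest stream at the calibration orientation, noise-free."""
    n, rate = 40, 20.0
    t = np.arange(n) / rate
    acc = np.tile([1.0, 0.0, 0.0], (n, 1))
    gyro = np.zeros((n, 3))
    return stream_from_arrays("chest_A", rate, t, acc, gyro)


@pytest.fixture(scope="session")
def default_session():
    return synthetic.simulate_session(seed=42)
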