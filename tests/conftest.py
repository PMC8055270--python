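import numpy as np
import pytest

import winghum as wh


@pytest.fixture(scope="session")
def medium():
    return wh.Medium()


@pytest.fixture(scope="session")
def hummingbird_model():
    """Synthetic hummingbird, long enough for 2.5 Hz band resolution."""
    return wh.make_model("hummingbird", n_periods=18)


@pytest.fixture(scope="session")
def hummingbird_model_short():
    """Synthetic hummingbird at the default 4-period simulation length."""
    return wh.make_model("hummingbird", n_periods=4)


@pytest.fixture(scope="session")
def oscillating_dipole():
    """Stationary vertical point force, 1 N peak at 44.2 Hz (classical dipole)."""
    n = 512
    tau = np.arange(n) / n
    F = np.zeros((n, 3))
    F[:, 2] = np.sin(2 * np.pi * tau)
    return wh.stationary_point_source(F, [0.0, 0.0, 0.0], 44.2, n, 4)
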