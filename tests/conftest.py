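import numpy as np
import pytest

from bordergrid import arena


@pytest.fixture(scope="session")
def square150():
    return arena.make_environment("rectangle", 150.0, 150.0)


@pytest.fixture(scope="session")
def square100():
    return arena.make_environment("rectangle", 100.0, 100.0)


@pytest.fixture(scope="session")
def trapezoid():
    return arena.make_environment(
        "right_trapezoid", width_cm=180.0, height_cm=90.0,
        trapezoid_short_wall_cm=135.0)


@pytest.fixture(scope="session")
def short_walk(square100):
    return arena.random_walk(square100, duration_s=30.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
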