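import numpy as np
import pytest

from wmwdesign import DesignSpec, load_fixture


@pytest.fixture(scope="session")
def epilepsy_pair():
    return load_fixture("epilepsy")


@pytest.fixture(scope="session")
def kidney_pair():
    return load_fixture("kidney")


@pytest.fixture(scope="session")
def nasal_table():
    return load_fixture("nasal")


@pytest.fixture(scope="session")
def albumin_table():
    return load_fixture("albumin")


@pytest.fixture(scope="session")
def design_08():
    return DesignSpec(alpha=0.05, power=0.80)


@pytest.fixture(scope="session")
def design_09():
    return DesignSpec(alpha=0.05, power=0.90)


def random_sample_pair(rng: np.random.Generator):
    """A random two-sample pair mixing tied (integer) and continuous data."""
    n1, n2 = rng.integers(4, 40, size=2)
    kind = rng.integers(0, 4)
    if kind == 0:
        return rng.normal(0.0, 1.0, n1), rng.normal(0.7, 1.5, n2)
    if kind == 1:
        return (rng.poisson(5, n1).astype(float),
                rng.poisson(8, n2).astype(float))
    if kind == 2:
        return (rng.integers(0, 4, n1).astype(float),
                rng.integers(0, 5, n2).astype(float))
    return rng.exponential(1.0, n1), rng.exponential(2.0, n2)
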