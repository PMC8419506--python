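import numpy as np
import pytest

from nexf import ParamVector, TypeICensoredSample, generate_censored_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def theta_unit():
    return ParamVector(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def theta_half():
    """The (0.5, 0.5, 0.5) point used throughout the Monte-Carlo work."""
    return ParamVector(0.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def random_thetas():
    """200 parameter triples drawn once from (0.1, 5)^3."""
    r = np.random.default_rng(7)
    return [ParamVector(*v) for v in r.uniform(0.1, 5.0, size=(200, 3))]


@pytest.fixture(scope="session")
def complete_sample(theta_half):
    return generate_censored_sample(theta_half, 80, seed=11)


@pytest.fixture(scope="session")
def censored_sample(theta_half):
    return generate_censored_sample(theta_half, 80, censor_time=1.5, seed=12)
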