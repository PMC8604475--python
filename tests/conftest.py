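import numpy as np
import pytest
from hypothesis import settings

from markovcea import CostUtilityModel, builtin_parameter_set

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return builtin_parameter_set()


@pytest.fixture(scope="session")
def model(params):
    return CostUtilityModel(params)


@pytest.fixture(scope="session")
def base_results(model):
    return model.run()


@pytest.fixture(scope="session")
def psa_results(model):
    """One shared 1,000-iteration PSA at the default seed."""
    return model.fit(n_iterations=1000, seed=2020)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_transition_matrix(rng, zeros=False):
    """Random row-stochastic 3x3 matrix, optionally with a zero pattern."""
    m = rng.uniform(0.0, 1.0, size=(3, 3))
    if zeros:
        mask = rng.uniform(size=(3, 3)) < 0.3
        m[mask] = 0.0
        for i in range(3):
            if m[i].sum() == 0:
                m[i, i] = 1.0
    return m / m.sum(axis=1, keepdims=True)
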