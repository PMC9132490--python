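import numpy as np
import pytest

from s2eir import ModelParameters, get_fixture


@pytest.fixture(scope="session")
def set_a() -> ModelParameters:
    return get_fixture("set_A").params


@pytest.fixture(scope="session")
def set_b() -> ModelParameters:
    return get_fixture("set_B").params


@pytest.fixture(scope="session")
def set_c() -> ModelParameters:
    return get_fixture("set_C").params


@pytest.fixture(scope="session")
def set_d() -> ModelParameters:
    return get_fixture("set_D").params


def draw_params(rng: np.random.Generator, require=None, max_tries=10000):
    """Random valid parameter set, optionally conditioned on a predicate."""
    for _ in range(max_tries):
        p = ModelParameters(
            B=float(rng.uniform(0.1, 5.0)),
            alpha=float(rng.uniform(0.05, 1.0)),
            m=float(rng.uniform(0.01, 1.0)),
            beta=float(rng.uniform(0.05, 1.0)),
            epsilon=float(rng.uniform(0.05, 1.0)),
            gamma1=float(rng.uniform(0.05, 1.0)),
            gamma2=float(rng.uniform(0.05, 1.0)),
            mu=float(rng.uniform(0.05, 1.0)),
            lam=float(rng.uniform(0.05, 1.0)),
        )
        if require is None or require(p):
            return p
    raise RuntimeError("could not draw parameters satisfying the predicate")
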