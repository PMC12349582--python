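import numpy as np
import pytest

from laidrivers.synthetic import CouplingParams, GridSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_spec() -> GridSpec:
    return GridSpec.default(4, 4)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """6-year 4x4 simulation with balanced driver dominance."""
    return simulate_dataset(small_spec, 6, CouplingParams(dominance_lambda=0.5), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
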