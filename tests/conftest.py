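import math

import numpy as np
import pytest

from seivd import TraitSet


@pytest.fixture(scope="session")
def rep_traits() -> TraitSet:
    """Representative one-step-regime traits used across dynamics tests."""
    return TraitSet(r=math.log(2) / 4, phi=1e-7, tau=1.0, n_exposed=99, burst_size=50.0)


@pytest.fixture(scope="session")
def small_traits() -> TraitSet:
    """Small-chain traits for cheap integrations."""
    return TraitSet(r=0.2, phi=1e-7, tau=1.0, n_exposed=4, burst_size=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
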