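import numpy as np
import pytest

from gcspec import GCFractions, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


@pytest.fixture
def symmetric_params():
    """Two-island parameter set from the quasi-equilibrium regime."""
    return ModelParams(l=20, u=0.0002, epsilon=0.01, z_c=0.8, m=0.015)


@pytest.fixture
def uniform_gc():
    return GCFractions(1.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def case1_gc():
    """One third of loci shared by all islands, the rest all-distinct."""
    return GCFractions(1 / 3, 0.0, 0.0, 0.0, 2 / 3)


@pytest.fixture
def case2_gc():
    """The three two-group configurations equally abundant."""
    return GCFractions(0.0, 1 / 3, 1 / 3, 1 / 3, 0.0)
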