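import numpy as np
import pytest

from reactoracle import ChemicalSpace, Compound, MCMCConfig, ReactivityVector, Theory
from reactoracle.synthetic import (
    make_diels_alder_space,
    make_named_reaction_space,
    make_passerini_space,
    simulate_log,
)


@pytest.fixture(scope="session")
def diels_alder():
    return make_diels_alder_space()


@pytest.fixture(scope="session")
def passerini():
    return make_passerini_space()


@pytest.fixture(scope="session")
def named_reactions():
    return make_named_reaction_space()


@pytest.fixture(scope="session")
def tiny_space():
    """Two compounds, arity 2: the smallest legal chemical space."""
    return ChemicalSpace((Compound("a", "alpha"), Compound("b", "beta")), arities=(2,))


@pytest.fixture(scope="session")
def tiny_reactive_log(tiny_space):
    """One observation: the single pair reacted."""
    return simulate_log(tiny_space, lambda e: ReactivityVector.binary(1))


@pytest.fixture
def fast_config():
    """Small MCMC budget for smoke-level posterior checks."""
    return MCMCConfig(seed=123, chains=2, warmup=300, draws=300)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230417)
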