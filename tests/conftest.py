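import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from reefrescue import (
    CompetitionMatrix,
    CoralParams,
    MacroalgaeParams,
    competition_preset,
)


@pytest.fixture
def coral():
    return CoralParams(V=0.05, beta=0.01)


@pytest.fixture
def macroalgae():
    return MacroalgaeParams()


@pytest.fixture
def bistable():
    return competition_preset("bistable")


@pytest.fixture
def coexistence():
    return competition_preset("coexistence")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
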