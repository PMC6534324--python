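import numpy as np
import pytest

from fragcycles import ModelParams, PayoffMatrix
from fragcycles.games import pd_example
from fragcycles.lifecycles import LifeCycle


@pytest.fixture
def pd3() -> PayoffMatrix:
    """The prisoner's-dilemma example matrix (1, -3, 3, 0): psi=1, phi=0."""
    return pd_example(3.0)


@pytest.fixture
def neutral_half() -> ModelParams:
    """Neutral dynamics (w=0) at m=1/2."""
    return ModelParams(m=0.5, w=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def lc(name: str) -> LifeCycle:
    return LifeCycle.from_name(name)
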