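import numpy as np
import pytest

from rterd import ParamSet

#: parameter grid used by normalization/ordering property tests
GRID_DELTAS = (0.1, 0.75, 1.5, 2.5, 3.75)
GRID_LAMS = (0.25, 0.5, 1.5, 2.5, 3.25)

#: the five parameter rows of the moments reference table
TABLE1_PARAMS = (
    (1.5, 2.5),
    (2.5, 1.5),
    (2.75, 0.25),
    (3.75, 1.25),
    (0.75, 3.25),
)


@pytest.fixture(scope="session")
def std_params() -> ParamSet:
    """The worked-example parameter pair used throughout the docs."""
    return ParamSet(delta=1.5, lam=2.5)


@pytest.fixture(scope="session")
def param_grid() -> list[ParamSet]:
    return [ParamSet(d, l) for d in GRID_DELTAS for l in GRID_LAMS]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
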