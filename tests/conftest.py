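import numpy as np
import pytest

from cccflux.thermo import BathConditions, solution_conditions


@pytest.fixture
def nd96() -> BathConditions:
    """Standard oocyte bath under the default prediction conditions."""
    return solution_conditions("ND96")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
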