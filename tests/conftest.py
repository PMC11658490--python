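import numpy as np
import pytest

import demrss


@pytest.fixture(scope="session")
def normal_pop():
    """Fixed Normal(5,1) population under the additive-error model."""
    return demrss.generate_population(demrss.normal(5, 1), 1000, error_sd=1.0, seed=42)


@pytest.fixture(scope="session")
def uniform_pop():
    return demrss.generate_population(demrss.uniform(0, 1), 1000, error_sd=1.0, seed=43)


@pytest.fixture()
def constant_pop():
    """Degenerate frame: every unit has the same study value."""
    x = np.linspace(0, 1, 50)
    return demrss.Population.from_xy(x, np.full(50, 7.5))
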