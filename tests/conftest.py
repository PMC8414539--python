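import numpy as np
import pytest

from fwtract import make_gradient_table


@pytest.fixture(scope="session")
def gtab33():
    """The reference acquisition: 32 directions at b = 1000 plus one b0."""
    return make_gradient_table(32, 1000.0, 1)


@pytest.fixture(scope="session")
def gtab7():
    """Minimal determined scheme: 6 directions plus one b0."""
    return make_gradient_table(6, 1000.0, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
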