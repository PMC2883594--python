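import numpy as np
import pytest

from cisevolve.fixtures import default_models


@pytest.fixture(scope="session")
def models():
    """The default study conditions (seeded synthetic matrix, consensus
    promoter model, calibrated K0/K0R)."""
    return default_models(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
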