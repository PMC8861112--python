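import numpy as np
import pytest

from quenchscan.quench_model import QuenchModelParams, standard_protocol


@pytest.fixture(scope="session")
def protocol_fsk():
    return standard_protocol(forskolin=True)


@pytest.fixture(scope="session")
def protocol_dmso():
    return standard_protocol(forskolin=False)


@pytest.fixture
def default_params():
    return QuenchModelParams(Vm=-40.0, G=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
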