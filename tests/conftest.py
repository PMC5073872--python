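import numpy as np
import pytest

from cardioflow.config import default_config


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_16)
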