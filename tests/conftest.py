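import numpy as np
import pytest

import lvscar
from lvscar.cycle import LoadingProtocol


@pytest.fixture(scope="session")
def default_cfg():
    return lvscar.default_config()


@pytest.fixture(scope="session")
def baseline_cfg():
    return lvscar.baseline_config()


@pytest.fixture(scope="session")
def postmi_model(default_cfg):
    return lvscar.build_model(default_cfg)


@pytest.fixture(scope="session")
def baseline_model(baseline_cfg):
    return lvscar.build_model(baseline_cfg)


@pytest.fixture(scope="session")
def fast_loading():
    """Coarse discretisation for unit tests of the cycle machinery."""
    return LoadingProtocol(n_increments=12, n_time_points=15, espvr_points=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
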