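import numpy as np
import pytest

import chemopod as cp


@pytest.fixture
def ring256():
    return cp.PerimeterMesh.circle(10.0, n_nodes=256)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_logs():
    import logging
    lg = logging.getLogger("chemopod")
    old = lg.level
    lg.setLevel(logging.CRITICAL)
    yield
    lg.setLevel(old)
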