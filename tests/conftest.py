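import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid2d():
    from clotflow.fields import Grid
    return Grid((24, 20), (1.2, 1.0))


@pytest.fixture
def grid2d_periodic():
    from clotflow.fields import Grid
    return Grid((32, 24), (2.0, 1.0), periodic=(True, False))
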