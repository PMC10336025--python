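import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copulacov as cc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230628)


@pytest.fixture
def gamma_low():
    """Low zero-inflation pair of margins from the standard simulation grid."""
    return cc.ZIBParams(0.10, 2 / 7, 7.0), cc.ZIBParams(0.25, 5 / 7, 7.0)


@pytest.fixture
def paired_sample(rng, gamma_low):
    gi, gj = gamma_low
    return cc.sample_pair(n=80, theta=1.5, gamma_i=gi, gamma_j=gj, rng=rng)
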