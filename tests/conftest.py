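import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_signals(rng):
    """Random, well-conditioned 60-frame, 5-parcel subject (TR 2 s)."""
    from cofluct.io import ParcelSignals

    data = rng.standard_normal((60, 5))
    return ParcelSignals("sub-small", data, [f"p{i}" for i in range(5)], 2.0)


@pytest.fixture
def zscored_small(small_signals):
    from cofluct.preprocess import zscore

    return zscore(small_signals)


@pytest.fixture
def partition5():
    from cofluct.io import NetworkPartition

    return NetworkPartition(
        {"p0": "SMN", "p1": "SMN", "p2": "DMN", "p3": "DMN", "p4": "OTHER"})
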