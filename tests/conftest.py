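import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference_tables():
    from surfvib.model_io import load_reference_tables

    return load_reference_tables()


@pytest.fixture
def lc_dG(reference_tables):
    lc, _ = reference_tables
    return [r.dG_c for r in lc]


@pytest.fixture
def hc_dG(reference_tables):
    _, hc = reference_tables
    return [r.dG_c for r in hc]
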