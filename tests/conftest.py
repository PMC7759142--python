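import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdproc import ResponseMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(c, ic, labels=None) -> ResponseMatrix:
    c = np.atleast_2d(c)
    labels = labels or tuple(f"d{i + 1}" for i in range(c.shape[1]))
    return ResponseMatrix(c_items=c, ic_items=np.atleast_2d(ic), pair_labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng) -> ResponseMatrix:
    """1,000 x (10+10) fair-coin response matrix."""
    return make_matrix(
        (rng.random((1000, 10)) < 0.5).astype(int),
        (rng.random((1000, 10)) < 0.5).astype(int),
    )
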