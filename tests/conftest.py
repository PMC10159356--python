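import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from cheatsplit.game import CoinfectionParameters, PayoffParameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _finite(lo, hi):
    return st.floats(lo, hi, allow_nan=False, allow_infinity=False)


@st.composite
def payoff_params(draw, e_min=0.0, e_max=10.0, require_b_gt_d=False):
    """Valid payoff sets: d >= a > c > 0, e >= 0, b > 0."""
    c = draw(_finite(0.01, 2.0))
    a = c + draw(_finite(0.01, 3.0))
    d = a + draw(_finite(0.0, 3.0))
    if require_b_gt_d:
        b = d + draw(_finite(0.01, 10.0))
    else:
        b = draw(_finite(0.01, 10.0))
    e = draw(_finite(e_min, e_max))
    return PayoffParameters(a=a, b=b, c=c, d=d, e=e)


@st.composite
def coinfection(draw, lo=0.01, hi=1.0):
    return CoinfectionParameters(beta=draw(_finite(lo, hi)))


@pytest.fixture
def rng():
    return np.random.default_rng(20230424)


def random_valid_params(rng, n, *, require_b_gt_d=False):
    """Vector draw of n valid payoff sets; returns a list."""
    c = rng.uniform(0.01, 2.0, n)
    a = c + rng.uniform(0.01, 3.0, n)
    d = a + rng.uniform(0.0, 3.0, n)
    b = d + rng.uniform(0.01, 10.0, n) if require_b_gt_d else rng.uniform(0.01, 10.0, n)
    e = rng.uniform(0.0, 10.0, n)
    return [
        PayoffParameters(a=a[i], b=b[i], c=c[i], d=d[i], e=e[i]) for i in range(n)
    ]
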