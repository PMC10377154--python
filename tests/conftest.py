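import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230713)


@pytest.fixture
def two_group_sine():
    """A clean two-group gene: group b is group a delayed by 2 time units."""
    rng = np.random.default_rng(7)
    ta = np.sort(rng.uniform(5, 15, 40))
    tb = np.sort(rng.uniform(5, 15, 40))
    ya = np.sin(2 * np.pi * ta / 10) + rng.normal(0, 0.1, ta.size)
    yb = np.sin(2 * np.pi * (tb - 2.0) / 10) + rng.normal(0, 0.1, tb.size)
    X = pd.DataFrame(
        {"time": np.r_[ta, tb], "group": ["a"] * ta.size + ["b"] * tb.size}
    )
    return X, np.r_[ya, yb]

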