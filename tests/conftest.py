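import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axisbreak import BreakWarning

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(autouse=True)
def _silence_break_warnings():
    # individual tests re-enable these with pytest.warns where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BreakWarning)
        yield
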