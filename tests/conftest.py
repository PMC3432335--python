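import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class ConstRng:
    """Stub generator returning a fixed value for every uniform draw."""

    def __init__(self, value: float):
        self.value = float(value)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def const_rng():
    return ConstRng
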