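import numpy as np
import pytest
from hypothesis import settings

from thetamcf import ModelParams, TruncationSpec

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trunc100() -> TruncationSpec:
    return TruncationSpec(100, 100)


@pytest.fixture(scope="session")
def workhorse_params() -> ModelParams:
    """Mean-driven point with O(1) noise used throughout: mu=0.5, sigma^2=1, tau=1."""
    return ModelParams(mu=0.5, sigma=1.0, tau=1.0)


@pytest.fixture(scope="session")
def workhorse_rate(workhorse_params, trunc100) -> float:
    from thetamcf import stationary_rate

    return stationary_rate(workhorse_params, trunc100)


def circular_distance(a: float, b: float) -> float:
    """Distance between two angles on the circle."""
    return abs(float(np.angle(np.exp(1j * (a - b)))))
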