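import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metabridge.quantify import StandardLibrary
from metabridge.synthetic import SyntheticStandardSpec, make_standard_library

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def coarse_axis() -> np.ndarray:
    """ppm axis covering reference (0 ppm) and the metabolite window, coarse for speed."""
    return np.arange(-0.5, 10.0, 0.002)


@pytest.fixture
def two_standard_library(coarse_axis) -> StandardLibrary:
    """Two standards with disjoint peak regions on the coarse axis."""
    specs = [
        SyntheticStandardSpec("alanine", [(1.5, 1.0, 0.004), (3.8, 0.6, 0.004)]),
        SyntheticStandardSpec("glucose", [(5.3, 0.8, 0.004), (7.2, 1.0, 0.004)]),
    ]
    return make_standard_library(specs, coarse_axis)
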