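import numpy as np
import pytest

from econetkit import ScenarioConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-year scenario shared by raster-stage tests."""
    config = ScenarioConfig(shape=(100, 100), years=(1990, 2000), seed=3)
    return generate_bundle(config)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study scenario (first year used by cross-scale checks)."""
    return generate_bundle(ScenarioConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
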