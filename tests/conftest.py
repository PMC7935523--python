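import numpy as np
import pytest
from hypothesis import settings

from shapebench.registry import ShapeRegistry, default_registry

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def registry() -> ShapeRegistry:
    return default_registry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
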