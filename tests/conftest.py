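import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitolong.refgenome import CircularReference, random_reference

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ref() -> CircularReference:
    """2-kb random circular reference used by the aligner unit tests."""
    return random_reference(2000, seed=12)


@pytest.fixture(scope="session")
def mt_ref() -> CircularReference:
    """rCRS-sized (16,569 bp) random circular reference."""
    return random_reference(16_569, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
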