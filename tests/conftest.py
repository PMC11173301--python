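import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: master seed for every stochastic recovery experiment in the suite
MASTER_SEED = 20240531


@pytest.fixture(scope="session")
def recovery_seeds() -> np.ndarray:
    """100 deterministic child seeds for repeated-generation experiments."""
    return np.random.default_rng(MASTER_SEED).integers(0, 2**31 - 1, size=100)


@pytest.fixture(scope="session")
def basis():
    from fxrspec import BasisSet

    return BasisSet.default()
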