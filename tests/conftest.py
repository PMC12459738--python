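import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lgcmtrial import GeneratorConfig, generate, time_basis

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis():
    return time_basis([0, 1, 2, 3])


@pytest.fixture(scope="session")
def small_trial():
    """A modest complete-data trial shared by tests that only need structure."""
    cfg = GeneratorConfig(n_exp=150, n_wait=150, dropout=(0, 0, 0, 0))
    return generate(cfg, seed=42)


@pytest.fixture(scope="session")
def default_trial():
    """One trial under the full default study conditions (with dropout)."""
    return generate(GeneratorConfig(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
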