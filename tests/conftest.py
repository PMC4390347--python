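import pytest
from hypothesis import HealthCheck, settings

from trapscreen.synthetic_screen import SyntheticScreenConfig, simulate_screen

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_screen():
    """A small null screen (no planted effects) shared across tests."""
    config = SyntheticScreenConfig(n_clones=60, seed=101)
    dataset, truth = simulate_screen(config)
    return config, dataset, truth
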