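import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from felanding.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 4 cats x 2 trials x 4 heights."""
    return GeneratorConfig(n_cats=4, trials_per_cat_per_height=2, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
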