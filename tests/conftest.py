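import numpy as np
import pytest

from drmediate.synthetic import GenerationConfig, generate_cohort


@pytest.fixture(scope="session")
def latent_config() -> GenerationConfig:
    """Large latent-scale (pre-rounding) cohort config: the structural model is
    exactly linear here, so closed-form truths are exact."""
    return GenerationConfig(n_subjects=20000, seed=7, discretize=False)


@pytest.fixture(scope="session")
def latent_cohort(latent_config):
    return generate_cohort(latent_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Small discretized cohort for interface-level tests."""
    return generate_cohort(GenerationConfig(n_subjects=600, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
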