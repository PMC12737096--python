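import numpy as np
import pytest

from gaitval import synthetic_cohort as sc


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def identity_study():
    """Noise-free cohort measured identically by both systems."""
    cfg = sc.CohortConfig(
        within_subject_sd={k: 0.0 for k in sc.TRIAL_NOISE_KEYS}, seed=11)
    measurements, truth = sc.generate_study(cfg)
    return cfg, measurements, truth


@pytest.fixture(scope="session")
def noisy_study():
    """Default cohort (trial noise at half the between-subject SD)."""
    cfg = sc.CohortConfig(seed=7)
    measurements, truth = sc.generate_study(cfg)
    return cfg, measurements, truth
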