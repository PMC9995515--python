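import numpy as np
import pytest

from rseeg.features import extract_features
from rseeg.synthetic import generate_recordings, study_config


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort config with the study's group effects."""
    return study_config(seed=7, n_per_group=4, duration=8.0,
                             sample_rate=250.0, planted=False)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    recordings, truth = generate_recordings(tiny_config)
    return recordings, truth


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    recordings, _ = tiny_cohort
    return extract_features(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230308)
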