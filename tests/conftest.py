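import warnings

import numpy as np
import pytest

from finclick.detect import DetectorConfig, train_classifier
from finclick.simulate import (ScenarioConfig, generate_minute_counts,
                               generate_spectra_dataset)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def spectra_small():
    """600 labelled spectra, enough for a well-behaved classifier."""
    return generate_spectra_dataset(600, 0.5, seed=1)


@pytest.fixture(scope="session")
def model(spectra_small, detector_config):
    return train_classifier(spectra_small, seed=5, config=detector_config)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced study scenario (720 minutes) for fast GLMM tests."""
    return ScenarioConfig(n_days=12, sessions_per_day=3,
                          minutes_per_session=20, seed=11)


@pytest.fixture(scope="session")
def small_counts(small_scenario):
    return generate_minute_counts(small_scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
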