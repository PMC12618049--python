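import numpy as np
import pytest

from saccmix import build_default_config, generate_experiment
from saccmix.pipeline import classify_experiment

# Fixed seed for the canonical synthetic experiment used across the suite.
EXPERIMENT_SEED = 7


@pytest.fixture(scope="session")
def default_config():
    return build_default_config()


@pytest.fixture(scope="session")
def default_experiment(default_config):
    """The full default experiment (25 subjects x 4 blocks x 120 trials)."""
    return generate_experiment(default_config, EXPERIMENT_SEED)


@pytest.fixture(scope="session")
def classified_default(default_experiment):
    """Event-level classification of the default experiment (no modes yet)."""
    return classify_experiment(default_experiment)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
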