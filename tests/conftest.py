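import numpy as np
import pytest

from chromopath.simulate import ClassParams, SimulationConfig, simulate_feature_table


def small_config(n_benign=150, n_malignant=400, seed=7, **kwargs):
    """Cohort-default class distributions at reduced sample sizes."""
    cfg = SimulationConfig(seed=seed, **kwargs)
    cfg.benign.n = n_benign
    cfg.malignant.n = n_malignant
    return cfg


@pytest.fixture(scope="session")
def feature_table():
    """A small synthetic cohort with the default class separation."""
    return simulate_feature_table(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
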