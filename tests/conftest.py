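import numpy as np
import pytest

from facecode.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 40-subject cohort shared across tests that only need shapes."""
    cfg = SimConfig(n_subjects=40, n_voxels=60, seed=7)
    subjects, patterns, truth = generate_cohort(cfg)
    return cfg, subjects, patterns, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
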