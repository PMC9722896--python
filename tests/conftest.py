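import numpy as np
import pytest

from srsboot.cohort import CohortConfig, generate_cohort
from srsboot.engine import EngineConfig, run_experiment


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, fixed seed, reused read-only across tests."""
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def tiny_experiment(small_cohort):
    """A small but real experiment result shared by downstream-module tests."""
    cfg = EngineConfig(n_trees=60)
    return run_experiment(small_cohort, "both", n_reps=8, seed=42, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
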