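import numpy as np
import pytest

import trajgwas as tg
from trajgwas.pipeline import outcome_tables


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small included cohort with phenotypes, shared across read-only tests."""
    cfg = tg.SimulationConfig(n_candidates=300, n_variants=60, seed=11)
    cohort, _ = tg.simulate_cohort(cfg)
    return cfg, cohort


@pytest.fixture(scope="session")
def tiny_outcomes(tiny_cohort):
    _, cohort = tiny_cohort
    std, tables = outcome_tables(cohort.phenotypes)
    return std, tables


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
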