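import numpy as np
import pytest
from hypothesis import settings

from crdgame import default_design, generate_experiment, loglinear

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment with the study design (seed 0)."""
    return generate_experiment(default_design(), seed=0)


@pytest.fixture(scope="session")
def replicate_tables():
    """Success tables and group outcomes for 200 replicate experiments."""
    tables, outcomes = [], []
    design = default_design()
    for seed in range(200):
        gameplay, _, _ = generate_experiment(design, seed)
        tables.append(loglinear.success_table(gameplay))
        outcomes.append(loglinear.group_outcomes(gameplay))
    return tables, outcomes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
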