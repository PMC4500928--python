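import numpy as np
import pytest
from hypothesis import settings

from seqstop.simulate import SimulationConfig, simulate_dataset
from seqstop.trials import reject_outliers

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_1000():
    """One clean 1000-trial dataset (non-skewed Stop generator, seed 42)."""
    ts, truth = simulate_dataset(SimulationConfig(n_trials=1000, seed=42))
    kept, _ = reject_outliers(ts)
    return kept, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
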