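import numpy as np
import pytest

from gaborient.experiments import run_monotonicity_experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def monotonicity_run():
    """One shared degradation-series run (jitter grid x 10 seeds, both
    methods); several slow checks read from it."""
    return run_monotonicity_experiment(master_seed=0)
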