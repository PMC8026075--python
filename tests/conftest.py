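import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import binsim

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_results() -> binsim.ExperimentResults:
    """One full 15-cell study at the scaled fidelity used by the test suite.

    20,000 trials per base-rate pair (n = 2000) and 200 K-median restarts;
    shared by every test that reads correlations, partitions or stability.
    """
    cfg = binsim.ExperimentConfig(
        simulation=binsim.SimulationConfig(trials=20_000, seed=1),
        restarts=200,
    )
    return binsim.BaseRateExperiment(cfg).run()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_similarity(rng: np.random.Generator, p: int) -> np.ndarray:
    """A random symmetric similarity matrix with row-maximal unit diagonal."""
    s = rng.random((p, p))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return s
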