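import numpy as np
import pytest

from cffrag.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small four-label cohort with full per-fragment tables."""
    config = SimulationConfig(
        n_per_group={"healthy": 6, "PN": 6, "AN": 6, "MPNST": 6},
        n_fragments=8000, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
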