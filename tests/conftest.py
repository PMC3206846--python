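import pytest

from symprofiler.simulate import SimulationParams, simulate_dataset

SMALL_PARAMS = SimulationParams(
    sources=(("hostA", 3), ("hostB", 3), ("seawater", 3)),
    dominant_fraction={"hostA": 0.34, "hostB": 0.51},
    generalist_fraction={"hostA": 0.3, "hostB": 0.4},
    n_seawater_otus=30,
    n_specialist_otus={"hostA": 12, "hostB": 8},
)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale synthetic dataset (9/3/3/9 samples x 15 clones)."""
    return simulate_dataset(seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast per-module tests."""
    return simulate_dataset(SMALL_PARAMS, seed=11)
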