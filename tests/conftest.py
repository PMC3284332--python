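import numpy as np
import pytest

from meiorec import simulate


@pytest.fixture(scope="session")
def small_map():
    return simulate.generate_marker_map(
        n_markers=1000, chromosome_length=1_000_000, clustering=1.0, seed=7)


@pytest.fixture(scope="session")
def tiny_map():
    """A handful of markers; cheap truth evaluation for count statistics."""
    return simulate.generate_marker_map(
        n_markers=10, chromosome_length=22_400_000, clustering=1.0, seed=3)


@pytest.fixture(scope="session")
def default_map():
    return simulate.generate_marker_map(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_map):
    params = simulate.SimulationParams()
    truths, calls = simulate.simulate_dataset(default_map, params, seed=11)
    return {"map": default_map, "params": params,
            "truths": truths, "calls": calls}


@pytest.fixture(scope="session")
def annotation():
    return simulate.generate_annotation(seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
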