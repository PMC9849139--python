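import numpy as np
import pytest

from npcassembly import (NupAssemblyModel, SimulationConfig,
                         make_toy_assembly_system, simulate_region_traces)


@pytest.fixture(scope="session")
def noisy_traces():
    """Default 10-Nup panel, 0.5-min grid, 1% noise."""
    return simulate_region_traces(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_traces():
    return simulate_region_traces(SimulationConfig(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def reduced_fit(noisy_traces):
    """One shared reduced-mode fit reused across test modules."""
    model = NupAssemblyModel(noisy_traces, mode="reduced")
    return model.fit(multistart=2, seed=0)


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_assembly_system(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
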