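import pytest

from tritract.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across tests (seed 1)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim_dir(default_sim, tmp_path_factory):
    """The default dataset written out to files."""
    d = tmp_path_factory.mktemp("simdata")
    paths = default_sim.write_all(d)
    return default_sim, paths
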