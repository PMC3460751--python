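import pytest

from polytag import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(n_loci=40, library_size=4000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(conspecific, heterospecific, contigs, truth) at desk scale."""
    return simulate.simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_lanes(small_sim, small_config):
    con, _, _, truth = small_sim
    return simulate.simulate_tag_lanes(con, truth, small_config)
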