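import pytest

from circflow import simulate as sim


@pytest.fixture(scope="session")
def cfg():
    return sim.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def truth(cfg):
    return sim.plant_circrnas(sim.generate_genome(cfg), cfg)


@pytest.fixture(scope="session")
def reads(truth, cfg):
    return sim.simulate_reads(truth, cfg)
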