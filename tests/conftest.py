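import dataclasses

import pytest

from rrbsdmf.simulate import SimulationConfig, generate_genome

#: seed of the standard synthetic study used across tests
STANDARD_SEED = 11


@pytest.fixture(scope="session")
def standard_config() -> SimulationConfig:
    """The standard study: 2 pairs, 2000 fragments, 200 shared planted DMFs,
    delta 0.5, coverage 30x, 88% planted hypermethylation."""
    return SimulationConfig(seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def standard_artifacts(standard_config):
    return generate_genome(standard_config)


@pytest.fixture(scope="session")
def null_artifacts():
    """A study with nothing planted: every fragment is a true null."""
    cfg = dataclasses.replace(
        SimulationConfig(seed=STANDARD_SEED), planted_delta=0.0, n_planted_dmf=0
    )
    return generate_genome(cfg)


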