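import pytest

from tailsolv import (
    GeneratorConfig,
    generate_construct,
    generate_ensemble,
)
from tailsolv.solvent_accessibility import relative_accessibility, residue_sasa
from tailsolv.synthetic_data import construct_segments


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        seed=11, core_length=30, tail_lengths=(16, 8), ensemble_size=3, noise_scale=0.4
    )


@pytest.fixture(scope="session")
def small_construct(small_config):
    return generate_construct(small_config)


@pytest.fixture(scope="session")
def small_segments(small_config):
    return construct_segments(small_config)


@pytest.fixture(scope="session")
def small_ensemble(small_config, small_construct):
    return generate_ensemble(small_construct, small_config)


@pytest.fixture(scope="session")
def small_table(small_construct):
    return relative_accessibility(residue_sasa(small_construct))
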