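import numpy as np
import pytest

from telofuse.core_io import PipelineConfig
from telofuse.simfusion import SimulatorConfig, make_test_reference
from telofuse.toymap import ToyMapper


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def mini_reference():
    """Small deterministic reference shared across tests (4 x 20 kb
    pseudo-chromosomes plus decoys and sub-telomeres)."""
    rng = np.random.default_rng(12345)
    return make_test_reference(rng, n_chroms=4, chrom_len=20_000)


@pytest.fixture(scope="session")
def mini_mapper(mini_reference):
    return ToyMapper(mini_reference.sequences)


@pytest.fixture()
def sim_config():
    return SimulatorConfig(n_events=30, rng_seed=11)
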