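import numpy as np
import pytest

from zwscan.config import SimConfig
from zwscan.simulate import simulate_dataset


@pytest.fixture(scope="session")
def clean_config():
    """Desk-scale config without genotyping noise (exact truth recovery)."""
    return SimConfig(seed=1, missing_rate=0.0, genotype_error_rate=0.0)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)


@pytest.fixture(scope="session")
def lof_rich_dataset():
    """Dataset with elevated LoF rates in every region (classifier stress)."""
    cfg = SimConfig(seed=3, missing_rate=0.0, genotype_error_rate=0.0,
                    lof_prob={"PAR": 0.3, "S2": 0.4, "S1": 0.5})
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
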