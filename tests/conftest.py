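import pytest

from lncprofile.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """Default-noise synthetic dataset (the study conditions)."""
    return generate_dataset(default_cfg)


@pytest.fixture(scope="session")
def noisefree_dataset(default_cfg):
    """Same dataset with replicate noise disabled."""
    return generate_dataset(default_cfg, noise_sd=0.0)
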