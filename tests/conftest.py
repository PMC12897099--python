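import logging

import numpy as np
import pytest

from foamdry.drying import build_drying_run
from foamdry.synthetic import SyntheticConfig, generate_run

# selection warnings ("no model meets...") are expected in noisy sweeps
logging.getLogger("foamdry.fitting").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_config() -> SyntheticConfig:
    return SyntheticConfig(noise_sd=0.01, seed=42)


@pytest.fixture(scope="session")
def noiseless_run_60(noiseless_config):
    """Reduced noise-free synthetic run at 60 °C."""
    series, truth = generate_run(noiseless_config, 60.0)
    return build_drying_run(series, noiseless_config.dry_mass), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
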