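import numpy as np
import pytest

from silofed.harmonize import harmonize_all
from silofed.synthetic_silos import default_obstetrics_config, generate


@pytest.fixture(scope="session")
def small_config():
    """Nine-silo study at 2% scale with covariate shift on."""
    return default_obstetrics_config(scale=0.02, seed=1, shift_strength=0.3)


@pytest.fixture(scope="session")
def small_silos(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def harmonized_study(small_config, small_silos):
    """(encoded silos, schema with ordinal map, selected targets)."""
    return harmonize_all(small_silos, small_config.schema)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
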