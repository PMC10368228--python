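import numpy as np
import pytest

from atacmod.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    return SyntheticConfig(
        n_cell_types=3,
        n_nuclei_per_sample=50,
        n_samples=2,
        n_peaks=200,
        n_tiles=300,
        n_genes=60,
        n_tfs=12,
        n_conditions=2,
        n_modules=3,
        seed=11,
    )
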