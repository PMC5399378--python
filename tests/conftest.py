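import numpy as np
import pytest

from mirforge.synthetic_data import SyntheticConfig, plant_genome


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted genome shared by track-level unit tests."""
    cfg = SyntheticConfig(genome_length=30_000, n_precursors=8,
                          n_repeat_copies=0, seed=11)
    genome, truth = plant_genome(cfg)
    return cfg, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
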