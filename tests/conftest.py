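import numpy as np
import pytest

from crossfeed.abm import SimConfig, SpeciesParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A desk-scale configuration: tiny grid, few agents, quick transfers."""
    return SimConfig(
        grid_width=8, grid_height=8,
        init_yeast=4, init_wt_bacteria=27, init_mutant_bacteria=1,
        doublings_per_transfer=3, n_transfers=3,
        max_ticks_per_transfer=500,
    )
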