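import numpy as np
import pytest

from cyclosense import synthetic_data as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def endo_exo_ensemble():
    """300-frame 70/30 endo/exo mixture with per-frame state labels."""
    cfg = syn.EnsembleConfig(n_frames=300, endo_fraction=0.7)
    return syn.gen_ensemble(cfg, seed=11)
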