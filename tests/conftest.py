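import numpy as np
import pytest
from hypothesis import settings

from plotvi.config import SyntheticConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """A small, fully deterministic trial: 2 bays x 4 plots x 3 stages."""
    return SyntheticConfig(
        n_bays=2, plots_per_bay=4, n_stages=3, plot_px=(10, 30),
        cover_curve=(0.0, 0.5, 1.0), senescence_curve=(0.0, 0.0, 0.5),
        noise_sd=0.0, cover_jitter_sd=0.0, senescence_jitter_sd=0.0,
        soil_gain_range=(1.0, 1.0), veg_gain_range=(1.0, 1.0), seed=7)


@pytest.fixture
def tiny_noisy_cfg(tiny_cfg):
    from dataclasses import replace

    return replace(tiny_cfg, noise_sd=0.01, cover_jitter_sd=0.1,
                   senescence_jitter_sd=0.05, soil_gain_range=(0.9, 1.1))
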