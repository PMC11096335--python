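import numpy as np
import pytest

from iscatflow import InstrumentConfig
from iscatflow import synthgen


@pytest.fixture
def small_cfg():
    """256x256 instrument geometry: same optics, desk-scale frames."""
    return InstrumentConfig(frame_shape=(256, 256))


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)


def make_sparse_frame(cfg, contrast, n_spots=25, seed=0, noise=True,
                      n_averaged=1, min_sep=15.0):
    """Frame with isolated equal-contrast spots; returns (frame, truth)."""
    r = np.random.default_rng(seed)
    spots = synthgen.random_spots(
        n_spots, tuple(cfg.frame_shape), r,
        contrast_sampler=lambda _: contrast,
        min_separation_px=min_sep, margin_px=12.0)
    return synthgen.simulate_frame(spots, cfg, shot_noise=noise,
                                   n_averaged=n_averaged, seed=seed + 1)
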