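import numpy as np
import pytest

import forkstat as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sparse_frame(seed: int, n_emitters: int = 10, photons: float = 1000.0,
                      background: float = 5.0, field_px: int = 64,
                      min_sep_px: float = 10.0):
    """One-frame movie with well-separated always-on emitters plus truth."""
    config = fs.SimConfig(field_size_px=(field_px, field_px),
                          background_photons_per_px=background,
                          n_frames=1, blink_on_rate=1.0, blink_off_rate=0.0,
                          seed=seed)
    truth = fs.random_emitters(config, n_emitters, seed=seed + 10_000,
                               photons_per_frame=photons,
                               min_separation_nm=min_sep_px * config.pixel_size_nm)
    movie = fs.simulate_movie(config, truth)
    return movie, truth, config
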