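import numpy as np
import pytest

from repliphase.simulate import MovieConfig, NoiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_movie_config(**overrides) -> MovieConfig:
    """A fast-to-render volumetric config used across imaging tests."""
    cfg = MovieConfig(
        n_nuclei=2,
        shape_xy=(120, 120),
        xy_pixel=0.3,
        z_range=6.4,
        z_step=0.4,
        nucleus_radius=3.0,
        psf_sigma=(0.2, 0.12, 0.12),
        seed=0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def noiseless(**kw) -> NoiseModel:
    return NoiseModel(enabled=False, **kw)
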