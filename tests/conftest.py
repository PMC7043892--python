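"""Shared fixtures: small synthetic movies generated at test time."""

import numpy as np
import pytest

from epiwound import synthgen
from epiwound.imgio import Movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_geometry():
    return synthgen.MovieGeometry(
        n_frames=30, height=64, width=64,
        pixel_size_um=0.1, frame_interval_s=0.5, background=10.0,
    )


@pytest.fixture()
def constant_movie():
    frames = np.full((20, 32, 32), 7.0)
    return Movie(frames, pixel_size_um=0.1, frame_interval_s=0.5)


@pytest.fixture()
def noiseless_comets(small_geometry):
    """Deterministic-speed comets, no noise: step lengths exact."""
    params = synthgen.CometParams(
        speed_um_s=0.2, speed_cv=0.0, n_comets_per_frame=5,
        lifetime_frames=10, amplitude=50.0, direction_mode="isotropic",
    )
    return synthgen.generate_comet_movie(params, small_geometry, seed=7)
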