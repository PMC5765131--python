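import numpy as np
import pytest

from binoica.gabor import GaborParams
from binoica.synthetic_data import SceneSpec, ViewingGeometry, render_stereo_pair


@pytest.fixture
def geometry():
    return ViewingGeometry(interocular_mm=65.0, fixation_mm=1000.0,
                           field_half_width_arcmin=200.0,
                           pixel_pitch_arcmin=1.0)


@pytest.fixture(scope="session")
def small_pair():
    """A small rendered stereo pair with a mild ground-plane depth profile."""
    geom = ViewingGeometry(interocular_mm=65.0, fixation_mm=10_000.0,
                           field_half_width_arcmin=200.0)
    scene = SceneSpec(eye_height_mm=1600.0, texture_alpha=1.0,
                      vertical_gain=2e-5, rng_seed=123)
    pair, truth = render_stereo_pair(scene, geom)
    return pair, truth, geom


def random_gabor_params(rng, amplitude=None):
    """Well-conditioned random canonical parameters for recovery tests."""
    return GaborParams(
        theta=rng.uniform(0.1, 3.0),
        f=rng.uniform(0.08, 0.3),
        phi=rng.uniform(0.3, 5.9),
        sigma_w=rng.uniform(2.0, 4.0),
        sigma_h=rng.uniform(2.0, 4.0),
        psi=rng.uniform(0.0, 3.0),
        centre_x=rng.uniform(-2.0, 2.0),
        centre_y=rng.uniform(-2.0, 2.0),
        amplitude=rng.uniform(0.5, 2.0) if amplitude is None else amplitude,
    )
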