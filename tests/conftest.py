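import numpy as np
import pytest

from ripplepond import DiscSpec, build_disc, make_test_set


@pytest.fixture(scope="session")
def full_disc():
    """The full-size characterization disc (200 arms x 200 per arm)."""
    return build_disc(DiscSpec(arms=200, per_arm=200, trials=1000, seed=42))


@pytest.fixture(scope="session")
def small_disc():
    return build_disc(DiscSpec(arms=8, per_arm=4, trials=50, seed=0))


@pytest.fixture(scope="session")
def image_set_100():
    """The synthetic mixed test set at acceptance scale."""
    return [img for _, img in make_test_set(100, seed=7)]


@pytest.fixture()
def filled_circle():
    """A centered filled circle on a 200x200 raster, radius 60 px."""
    size = 200
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (np.hypot(xx - c, yy - c) <= 60).astype(float)
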