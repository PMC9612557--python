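import numpy as np
import pytest

from colonyscope import GrowthParams, MigrationParams, fov_from_camera, paper_fov


@pytest.fixture(scope="session")
def camera_fov():
    """The study's camera geometry (1024 x 1024 px at 216.7 nm/px)."""
    return paper_fov()


@pytest.fixture(scope="session")
def small_fov():
    """A small rendering geometry (binned camera) used for fast image tests."""
    return fov_from_camera(256, 256, 0.65)


@pytest.fixture()
def growth():
    return GrowthParams()


@pytest.fixture()
def migration():
    return MigrationParams.per_minute()


def mc_disk_fraction(cx, cy, radius, fov, n, rng):
    """Monte-Carlo oracle: fraction of uniform points in the disk that fall
    inside the FOV rectangle, plus its standard error."""
    u = rng.random(n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    r = radius * np.sqrt(u)
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    inside = (np.abs(x) <= fov.half_width) & (np.abs(y) <= fov.half_height)
    frac = inside.mean()
    se = inside.std(ddof=1) / np.sqrt(n)
    return frac, se
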