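import numpy as np
import pytest

from fcoat import (
    DetectionAperture,
    OpticalConfig,
    build_segment_grid,
)


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_config():
    # quarter-size grid, same focal pixel pitch as the default geometry
    return OpticalConfig(grid_n=64, pupil_diameter_px=32)


@pytest.fixture(scope="session")
def layout32(config):
    return build_segment_grid(config, 32)


@pytest.fixture(scope="session")
def pinhole():
    """Single-pixel-scale detection aperture at the target."""
    return DetectionAperture(center_um=(0.0, 0.0), radius_um=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
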