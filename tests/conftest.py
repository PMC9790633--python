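import numpy as np
import pytest

import fundusvessel as fv


@pytest.fixture
def disc() -> fv.DiscGeometry:
    """Geometry matching the default SimSpec (annulus radii 72..144 px)."""
    return fv.DiscGeometry(center=(160.0, 160.0), disc_radius=36.0)


@pytest.fixture
def uniform_image() -> fv.FundusImage:
    return fv.FundusImage(np.full((320, 320), 50.0), bit_depth=8)


def pytest_configure(config):
    config.addinivalue_line("markers", "slow: longer simulation-based checks")
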