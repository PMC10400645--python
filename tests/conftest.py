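import numpy as np
import pytest

from spintrack.synthcell import rasterize_ellipse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipse_mask():
    """Rasterized ellipse factory in a 150x150 frame (semi-axes 25/12 default)."""

    def make(alpha_deg, a=25.0, b=12.0, center=(74.5, 74.5), shape=(150, 150)):
        return rasterize_ellipse(shape, np.asarray(center, dtype=float), a, b, alpha_deg)

    return make
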