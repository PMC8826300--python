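import numpy as np
import pytest

from avfsi.grid import UniformGrid


@pytest.fixture
def unit_grid():
    """64x64 grid over [-1, 1]^2 cm."""
    return UniformGrid(64, 64, 2.0 / 64, -1.0, -1.0)


@pytest.fixture
def circle():
    """Closed 200-gon approximating the radius-0.5 circle."""
    th = np.linspace(0.0, 2 * np.pi, 201)[:-1]
    return np.column_stack([0.5 * np.cos(th), 0.5 * np.sin(th)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
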