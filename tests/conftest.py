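import numpy as np
import pytest

from tvseg.preprocessing import GradientField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gradient_field(magnitude, direction):
    """Assemble a GradientField from magnitude/direction (tests only)."""
    magnitude = np.asarray(magnitude, dtype=float)
    direction = np.asarray(direction, dtype=float)
    return GradientField(
        magnitude=magnitude,
        direction=direction,
        gh=magnitude * np.cos(direction),
        gv=magnitude * np.sin(direction),
    )


@pytest.fixture
def dark_disk():
    """A dark disk (radius 8) on a light background, with its geometry."""
    h = w = 48
    center = (24.0, 24.0)
    radius = 8.0
    rr, cc = np.mgrid[:h, :w]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    gray = np.where(inside, 0.15, 0.95)
    return gray, center, radius, inside
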