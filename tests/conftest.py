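import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def random_physical_stokes(rng: np.random.Generator):
    """A uniformly random physical Stokes vector (polarized part inside the
    Poincaré ball of radius s1)."""
    from cardiopol import StokesVector

    s1 = rng.uniform(0.1, 10.0)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = s1 * rng.uniform(0.0, 1.0) ** (1 / 3)
    s2, s3, s4 = radius * direction
    return StokesVector(s1, s2, s3, s4)


def closed_form_sweep(d, angles_deg, i0=1000.0, gain=1.0):
    """Independent oracle for the noiseless optical train: an unpolarized
    source behind a rotating polarizer, isotropic depolarizer d and a
    horizontal analyzer gives I(theta) = (i0*gain/4) * (1 + d*cos 2theta)."""
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    return (i0 * gain / 4.0) * (1.0 + d * np.cos(2 * theta))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
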