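import numpy as np
import pytest

from dods.profile import BeamProfile

# derandomised hypothesis profile so the suite is reproducible
try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def bead_beam() -> BeamProfile:
    """Beam geometry from the bead calibration: omega0 = 280 nm,
    z0 = 1285 nm."""
    return BeamProfile(z_c=0.0, z0=1.285, omega0=0.280, i_max=100.0, i_bg=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
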