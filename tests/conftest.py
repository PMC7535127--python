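import numpy as np
import pytest
from hypothesis import settings

from atrialrd import AFK_AF_DEFAULT, calibrate_cv

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from atrialrd.synth import LAGeometrySpec, make_la_shell


@pytest.fixture(scope="session")
def calibrated_cell():
    """Default cell set with tau_d pinned so CV(D=0.1, dx=0.3) = 0.6 m/s."""
    return calibrate_cv(0.6, AFK_AF_DEFAULT)


@pytest.fixture(scope="session")
def small_shell_spec():
    """Coarse desk-scale LA shell spec shared by geometry-heavy tests."""
    return LAGeometrySpec(semi_axes_mm=(16.0, 13.0, 11.0), dx=0.8)


@pytest.fixture(scope="session")
def small_shell(small_shell_spec):
    return make_la_shell(small_shell_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
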