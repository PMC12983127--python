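import numpy as np
import pytest

from mqmri.cest import CESTGeometry
from mqmri.phantom import build_phantom
from mqmri.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 WT phantom shared by read-only tests."""
    return build_phantom((16, 16, 16), "WT", seed=3)


@pytest.fixture(scope="session")
def cest_geometry_small():
    """Two CEST slices centered on the 16-slice phantom."""
    return CESTGeometry(n_slices=2, z0_mm=1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
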