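import numpy as np
import pytest

from taskcbct.geometry import CArmGeometry, ViewPose
from taskcbct.phantom import MaterialPhantom, canonical_phantom
from taskcbct.projector import spectrum_preset


@pytest.fixture(scope="session")
def geom():
    return CArmGeometry()


@pytest.fixture(scope="session")
def spectrum():
    return spectrum_preset("poly5", 1.0e5)


@pytest.fixture(scope="session")
def mono_spectrum():
    return spectrum_preset("mono60", 1.0e5)


@pytest.fixture(scope="session")
def phantom():
    """Canonical two-screw phantom (deterministic layout)."""
    return canonical_phantom()


@pytest.fixture(scope="session")
def air_phantom():
    """All-air volume with an exactly centered voxel on the rotation axis."""
    return MaterialPhantom(
        np.zeros((65, 65, 65), dtype=np.uint8), (1, 1, 1), (-32.0, -32.0, -32.0)
    )
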