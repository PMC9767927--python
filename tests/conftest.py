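import numpy as np
import pytest

from gnrtrack import synthetic_data as sd


@pytest.fixture(scope="session")
def ref_cal():
    """The reference two-channel calibration (counts / radians)."""
    return sd.REFERENCE_CALIBRATION


@pytest.fixture()
def motion():
    """Default coupled biaxial motion: 0.5 um/s, 0.7-um pitch, cw yaw."""
    return sd.default_motion_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
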