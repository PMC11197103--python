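import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmrconf.spin_system import AcquisitionParams, SpinSystem, SymmetryGroup

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hf_pair() -> SpinSystem:
    """Two-spin heteronuclear HF system (first-order)."""
    return SpinSystem(
        spins=("1H", "19F"),
        shifts_ppm=[4.5, -180.0],
        j_hz=np.array([[0.0, 48.0], [48.0, 0.0]]),
        base_frequency_mhz=500.0,
    )


@pytest.fixture
def abx_system() -> SpinSystem:
    """Three-spin strongly coupled mixed system (2 ¹H + 1 ¹⁹F)."""
    return SpinSystem(
        spins=("1H", "1H", "19F"),
        shifts_ppm=[3.00, 3.03, -180.0],
        j_hz=np.array([
            [0.0, 9.0, 48.0],
            [9.0, 0.0, 11.0],
            [48.0, 11.0, 0.0],
        ]),
        base_frequency_mhz=500.0,
    )


@pytest.fixture
def rotor_system() -> SpinSystem:
    """Methyl rotor (3 equivalent ¹H) coupled to one CH proton."""
    j = np.zeros((4, 4))
    j[[0, 1, 2], 3] = 7.2
    j[3, [0, 1, 2]] = 7.2
    return SpinSystem(
        spins=("1H",) * 4,
        shifts_ppm=[1.2, 1.2, 1.2, 3.6],
        j_hz=j,
        base_frequency_mhz=500.0,
        symmetry_groups=[SymmetryGroup((0, 1, 2), "S3")],
    )


@pytest.fixture
def short_acq() -> AcquisitionParams:
    return AcquisitionParams("1H", 512, 1024, 0.5, 3.0, 0.5)
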