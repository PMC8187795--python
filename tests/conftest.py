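import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from camfuse import ConfidenceConfig, Homography, build_confidence_system, default_rig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The calibrated two-camera homography used as a concrete matrix fixture
#: (left/camera-2 plane onto right/camera-1 plane, h33 = 1).
CALIBRATED_H_ENTRIES = [
    [9.29968576e-01, -8.34785721e-01, 3.28368011e+02],
    [3.21580417e-01, 9.89425377e-01, -3.15245367e+02],
    [-7.93435882e-05, 5.73575359e-05, 1.0],
]


@pytest.fixture(scope="session")
def calibrated_h() -> Homography:
    return Homography(np.array(CALIBRATED_H_ENTRIES))


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def config() -> ConfidenceConfig:
    return ConfidenceConfig.default()


@pytest.fixture(scope="session")
def system(config):
    return build_confidence_system(config)
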