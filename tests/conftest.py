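import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panoct.eye_model import GULLSTRAND_NEWBORN
from panoct.protocol import ScanProtocol
from panoct.scan_geometry import ScanGeometry
from panoct.synthetic import SyntheticScene

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def newborn_eye():
    return GULLSTRAND_NEWBORN


@pytest.fixture(scope="session")
def default_geom(newborn_eye):
    """Pivot-on-iris geometry of the newborn eye: r = 8.725 mm, a = 6.125 mm."""
    return ScanGeometry.for_eye(newborn_eye)


@pytest.fixture(scope="session")
def small_protocol():
    """Narrow scan pattern sized for fast synthetic tests."""
    return ScanProtocol(n_ascans_per_bscan=33, n_bscans=7, samples_per_ascan=512,
                        sampling_rate_hz=None)


@pytest.fixture
def quiet_scene(newborn_eye):
    """Noiseless narrow-field retina scene for geometry-level checks."""
    geom = ScanGeometry.for_eye(newborn_eye, fov_deg=30.0)
    return SyntheticScene(eye=newborn_eye, geom=geom, speckle_mode="none",
                          rolloff_db_per_mm=0.0, noise_floor=1e-3, seed=11)


def ray_sphere_oracle(r, a, alpha_deg):
    """Independent vector ray/sphere intersection: explicit quadratic via
    np.roots, returning (chord length, central angle deg)."""
    alpha = np.deg2rad(alpha_deg)
    P = np.array([0.0, 0.0, a])
    D = np.array([np.sin(alpha), 0.0, -np.cos(alpha)])
    roots = np.roots([1.0, 2.0 * (P @ D), P @ P - r * r])
    t = float(np.max(roots.real))
    pt = P + t * D
    beta = float(np.degrees(np.arccos(np.clip(-pt[2] / r, -1.0, 1.0))))
    return t, beta
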