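import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ulnadiff.mesh_io import SurfaceMesh
from ulnadiff.synthetic import UlnaParams, generate_pair, generate_ulna

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tetrahedron() -> SurfaceMesh:
    """Unit tetrahedron, the smallest closed triangulated surface."""
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(v, f)


@pytest.fixture(scope="session")
def fast_params() -> UlnaParams:
    """Reduced-resolution ulna parameters for quick geometric tests."""
    return UlnaParams(axial_resolution=40, radial_resolution=16)


@pytest.fixture(scope="session")
def ulna_with_truth(fast_params):
    """One noise-free synthetic right ulna plus its ground-truth landmarks."""
    return generate_ulna(fast_params)


@pytest.fixture(scope="session")
def pair_plus3(fast_params):
    """Noise-free left/right pair with an imposed +3 mm difference."""
    return generate_pair(fast_params, 3.0)


def rigid_rotation(axis, angle):
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
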