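import numpy as np
import pytest

from femver.geometry import RigidTransform
from femver.synthetic import FemurSpec, generate_femur, generate_postop


def rotation_matrix(axis, degrees):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    a = np.radians(degrees)
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


@pytest.fixture(scope="session")
def default_spec():
    return FemurSpec()


@pytest.fixture(scope="session")
def default_femur(default_spec):
    """Default synthetic femur (CF present, Table-2-like angles) + truth."""
    return generate_femur(default_spec)


@pytest.fixture(scope="session")
def default_frame(default_femur):
    from femver.morphometry import build_frame

    model, _ = default_femur
    return build_frame(model)


@pytest.fixture(scope="session")
def default_record(default_femur, default_frame):
    from femver.morphometry import measure_hip

    model, _ = default_femur
    return measure_hip(model, hip_id="default", frame=default_frame)


@pytest.fixture(scope="session")
def displaced_postop(default_femur):
    """Postoperative model at the CF-group mean stem anteversion, displaced by
    a known rigid transform so measurement must register it back."""
    model, _ = default_femur
    disp = RigidTransform(rotation_matrix([0.3, 0.5, 0.8], 7.0), np.array([5.0, 3.0, 2.0]))
    return generate_postop(model, 26.7, disp), disp


@pytest.fixture(scope="session")
def coarse_femur():
    """Low-resolution femur for fast I/O and pipeline tests."""
    spec = FemurSpec(H=70.0, shaft_length=250.0)
    return generate_femur(spec, n_boundary=96)
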