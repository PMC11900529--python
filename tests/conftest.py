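import math

import numpy as np
import pytest

from utopioid.compounds import build_utopioid
from utopioid.geometry import Frame, RingSelection


@pytest.fixture(scope="session")
def u48800():
    return build_utopioid("U-48800")


@pytest.fixture(scope="session")
def u51754():
    return build_utopioid("U-51754")


def ideal_chair_ring(bond: float = 1.54) -> np.ndarray:
    """Analytic cyclohexane chair: equal bonds, exact tetrahedral angles.

    Projected radius rho = 2*sqrt(2)*b/3 and alternating out-of-plane
    displacements z0 = b/6 solve cos(angle) = -1/3 for the ring internal
    angles.
    """
    rho = 2.0 * math.sqrt(2.0) * bond / 3.0
    z0 = bond / 6.0
    pts = []
    for j in range(6):
        a = 2.0 * math.pi * j / 6.0
        pts.append([rho * math.cos(a), rho * math.sin(a), z0 * (-1.0) ** j])
    return np.array(pts)


@pytest.fixture(scope="session")
def chair_ring():
    return ideal_chair_ring()


@pytest.fixture()
def hexagon_frame():
    pts = [
        [math.cos(2 * math.pi * j / 6), math.sin(2 * math.pi * j / 6), 0.0]
        for j in range(6)
    ]
    frame = Frame(np.array(pts), ["C"] * 6)
    return frame, RingSelection(tuple(range(6)))


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(0.0, 10.0, size=3)
    return rot, shift
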