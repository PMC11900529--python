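"""Per-frame ring geometry: plane fits, C-H angles, puckering, dihedrals.

The axial/equatorial character of a cyclohexane proton is read off the
signed angle between its C-H bond and the least-squares plane of the six
ring carbons: axial bonds stand nearly perpendicular to that plane
(|angle| near 90 deg), equatorial ones lie nearly in it.  Chair/boat
classification uses the standard amplitude-phase decomposition of the
ring's out-of-plane displacements (total amplitude Q, polar angle theta,
pseudorotation phase phi): a chair concentrates amplitude in the
alternating q3 mode (theta near 0 or 180 deg), a boat/twist-boat in the
q2 mode (theta near 90 deg) with phi selecting the orientation around
the pseudorotation wheel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Frame",
    "RingSelection",
    "PlaneFit",
    "PuckerCoords",
    "AngleMeasurement",
    "GeometryError",
    "fit_plane",
    "ch_plane_angle",
    "classify_position",
    "pucker_coords",
    "dihedral",
    "AXIAL",
    "EQUATORIAL",
]

AXIAL = "axial"
EQUATORIAL = "equatorial"

CHAIR = "chair"
BOAT = "boat"
TWIST_BOAT = "twist-boat"
PLANAR = "planar"


class GeometryError(ValueError):
    """Degenerate geometry (collinear ring, zero-length bond...)."""


@dataclass
class Frame:
    """One conformer: N x 3 coordinates (Angstrom) plus atom metadata."""

    coords: np.ndarray
    elements: List[str]
    labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError(f"coordinates must be N x 3, got {self.coords.shape}")
        if len(self.elements) != len(self.coords):
            raise GeometryError("elements/coordinates length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def index_of(self, label: str) -> int:
        if self.labels is None:
            raise KeyError("frame has no atom labels")
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not found in frame") from None


@dataclass
class RingSelection:
    """Six ring-atom indices in traversal order, plus carbon -> hydrogens map."""

    ring: Tuple[int, ...]
    h_map: Dict[int, List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ring = tuple(int(i) for i in self.ring)
        if len(self.ring) != 6 or len(set(self.ring)) != 6:
            raise GeometryError(f"ring selection needs 6 distinct indices: {self.ring}")


@dataclass(frozen=True)
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray
    rms: float


@dataclass(frozen=True)
class PuckerCoords:
    """Amplitude-phase puckering coordinates of a six-membered ring."""

    Q: float
    theta: float  # deg, [0, 180]
    phi: float  # deg, [0, 360)
    q2: float
    q3: float
    planar: bool
    conformation: str  # chair | boat | twist-boat | planar


@dataclass(frozen=True)
class AngleMeasurement:
    carbon_label: str
    hydrogen_slot: int
    angle: float  # signed deg, [-90, 90]


def fit_plane(frame: Frame, ring: RingSelection) -> PlaneFit:
    """Orthogonal least-squares plane through the six ring atoms.

    The normal is the smallest principal direction of the centred ring
    coordinates; its sign is fixed so that it has a positive dot product
    with (atom1 - centroid) x (atom2 - centroid), the first two atoms in
    ring traversal order — i.e. a right-hand rule on the ring ordering.
    """
    pts = frame.coords[list(ring.ring)]
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-10:
        raise GeometryError("ring atoms are collinear; no plane defined")
    normal = vt[2]
    orient = np.cross(centred[0], centred[1])
    if np.linalg.norm(orient) < 1e-12:
        orient = np.cross(centred[1], centred[2])
    if float(orient @ normal) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(centroid, normal / np.linalg.norm(normal), rms)


def ch_plane_angle(plane: PlaneFit, c: np.ndarray, h: np.ndarray) -> float:
    """Signed angle (deg) between the C->H line and the fitted plane.

    +90 deg when C->H points along the plane normal, 0 when it lies in
    the plane, negative on the far side.
    """
    v = np.asarray(h, float) - np.asarray(c, float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise GeometryError("zero-length C-H vector")
    sin_angle = float(np.clip(v @ plane.normal / norm, -1.0, 1.0))
    return math.degrees(math.asin(sin_angle))


def classify_position(mean_angle: float, threshold: float = 45.0) -> str:
    """Axial iff |mean angle| >= threshold (boundary inclusive)."""
    if abs(mean_angle) > 90.0 + 1e-9:
        raise GeometryError(f"|angle| must be <= 90 deg, got {mean_angle}")
    return AXIAL if abs(mean_angle) >= threshold else EQUATORIAL


def _ring_displacements(frame: Frame, ring: RingSelection) -> np.ndarray:
    """Out-of-plane displacements z_j in the mean-plane frame.

    The reference frame follows the classic puckering construction: the
    origin is the ring centroid and the normal comes from the two
    in-plane direction sums R' = sum r_j sin(2 pi j / 6) and
    R'' = sum r_j cos(2 pi j / 6), which guarantees the two lowest
    Fourier components of z vanish.
    """
    pts = frame.coords[list(ring.ring)]
    centred = pts - pts.mean(axis=0)
    j = np.arange(6)
    rp = (centred * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (centred * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    # right-hand rule on the ring traversal order (matches fit_plane)
    normal = np.cross(rpp, rp)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise GeometryError("degenerate ring: puckering frame undefined")
    return centred @ (normal / nn)


def pucker_coords(
    frame: Frame,
    ring: RingSelection,
    planar_cutoff: float = 0.05,
    theta_chair: float = 30.0,
    phi_window: float = 15.0,
) -> PuckerCoords:
    """Puckering amplitudes (Q, theta, phi) and conformation class.

    For the six-membered ring the displacements decompose into a single
    pseudorotation pair (q2, phi) and an alternating amplitude q3:

        q2 cos phi =  sqrt(1/3) sum_j z_j cos(4 pi j / 6)
        q2 sin phi = -sqrt(1/3) sum_j z_j sin(4 pi j / 6)
        q3         =  sqrt(1/6) sum_j (-1)^j z_j
        Q = sqrt(q2^2 + q3^2),  theta = atan2(q2, q3)

    Classes: planar when Q < ``planar_cutoff`` (Angstrom); chair when
    theta < ``theta_chair`` or > 180 - ``theta_chair``; otherwise boat
    when phi is within ``phi_window`` of a multiple of 60 deg and
    twist-boat when within ``phi_window`` of 30 + a multiple of 60.
    """
    z = _ring_displacements(frame, ring)
    j = np.arange(6)
    q2c = math.sqrt(1 / 3) * float(z @ np.cos(4 * np.pi * j / 6))
    q2s = -math.sqrt(1 / 3) * float(z @ np.sin(4 * np.pi * j / 6))
    q3 = math.sqrt(1 / 6) * float(z @ (-1.0) ** j)
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)

    if Q < planar_cutoff:
        return PuckerCoords(Q, 0.0, 0.0, q2, q3, True, PLANAR)

    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0 if q2 > 1e-12 else 0.0
    if phi >= 360.0 - 1e-9:
        phi = 0.0

    if theta < theta_chair or theta > 180.0 - theta_chair:
        conf = CHAIR
    else:
        dist_boat = min(abs(((phi - 60.0 * k) + 180.0) % 360.0 - 180.0) for k in range(6))
        conf = BOAT if dist_boat <= phi_window else TWIST_BOAT
    return PuckerCoords(Q, theta, phi, q2, q3, False, conf)


def invert_pucker(Q: float, theta: float, phi: float) -> np.ndarray:
    """Out-of-plane displacements z_j realising target (Q, theta, phi).

    Exact inverse of :func:`pucker_coords` for a ring whose projected
    positions form a regular hexagon.
    """
    if Q < 0:
        raise GeometryError(f"puckering amplitude must be >= 0, got {Q}")
    th, ph = math.radians(theta), math.radians(phi)
    q2, q3 = Q * math.sin(th), Q * math.cos(th)
    j = np.arange(6)
    return np.asarray(
        math.sqrt(1 / 3) * q2 * np.cos(ph + 4 * np.pi * j / 6)
        + math.sqrt(1 / 6) * q3 * (-1.0) ** j
    )


def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Signed torsion angle p1-p2-p3-p4 in (-180, 180] degrees.

    IUPAC convention: looking from p2 towards p3, a clockwise rotation
    from the p2->p1 projection to the p3->p4 projection is positive.
    Syn-planar = 0, anti-planar = 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-12:
        raise GeometryError("coincident consecutive points")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear triple: dihedral undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang
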