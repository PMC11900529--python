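"""Synthetic conformer ensembles standing in for an MD trajectory.

The generator emulates the statistical structure of a solute-tempering
trajectory of a 2-aminocyclohexyl scaffold: a categorical mixture of ring
conformers (two chairs related by ring flip, rarer boats), thermal noise
on the puckering angles and Cartesian jitter on every atom, random rigid
placement of each frame, and — for the benzylic fragment — a bimodal
exocyclic dihedral with modes of either sign.  Rings carry explicit
hydrogens placed by local tetrahedral construction and heavy-atom stubs
at the two substituted carbons (C-1' amide side, C-6' amine side), so
the downstream alignment/RMSD/clustering chain sees the same degrees of
freedom it would in a real trajectory.  Every frame records its
ground-truth component, enabling exact confusion matrices in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import Ensemble
from .geometry import Frame, GeometryError, RingSelection, invert_pucker

__all__ = [
    "SynthesisConfig",
    "DihedralMode",
    "make_ring_frame",
    "make_ensemble",
    "make_dihedral_ensemble",
    "CANONICAL_TARGETS",
    "IDEAL_CHAIR_Q",
]

#: puckering amplitude of an ideal (tetrahedral, equal-bond) chair:
#: alternating displacements b/6 give Q = b / sqrt(6)
IDEAL_CHAIR_Q = 1.54 / math.sqrt(6.0)

#: canonical (Q, theta, phi) targets by conformer-class name
CANONICAL_TARGETS: Dict[str, Tuple[float, float, float]] = {
    "chair": (IDEAL_CHAIR_Q, 0.0, 0.0),
    "chair-flipped": (IDEAL_CHAIR_Q, 180.0, 0.0),
    "boat": (IDEAL_CHAIR_Q, 90.0, 0.0),
    "twist-boat": (IDEAL_CHAIR_Q, 90.0, 30.0),
    "planar": (0.0, 0.0, 0.0),
}

#: tetrahedral half-angle: the two out-of-ring bonds at a CH2 carbon open
#: by 2*beta with cos(2*beta) = -1/3
_BETA = 0.5 * math.acos(-1.0 / 3.0)

RING_LABELS = ["C-1'", "C-2'", "C-3'", "C-4'", "C-5'", "C-6'"]


@dataclass(frozen=True)
class DihedralMode:
    """One wrapped-normal component of the exocyclic dihedral law."""

    mean: float  # deg
    sd: float  # circular SD, deg
    weight: float


@dataclass
class SynthesisConfig:
    """Study conditions for a synthetic ring ensemble.

    ``components`` holds (conformer spec, weight) pairs where a spec is a
    canonical class name or an explicit (Q, theta, phi) triple; weights
    must sum to 1.  ``substituents`` maps ring position (0-based, ring
    order) to a stub slot: -1 places the heavy-atom stub in the lower
    hydrogen slot, +1 in the upper.  The default — stub lower at C-1',
    upper at C-6' — makes both substituents equatorial in the theta=0
    chair and axial in the flipped chair, the trans-diamine ring-flip
    behaviour of the real scaffold.
    """

    components: List[Tuple[Union[str, Tuple[float, float, float]], float]] = field(
        default_factory=lambda: [
            ("chair", 0.8725),
            ("chair-flipped", 0.1134),
            ("boat", 0.0141),
        ]
    )
    n_frames: int = 1000
    seed: int = 0
    bond_length: float = 1.54
    ch_bond: float = 1.09
    stub_bond: float = 1.47
    stub_element: str = "N"
    substituents: Dict[int, int] = field(default_factory=lambda: {0: -1, 5: +1})
    angular_noise_sd: float = 6.0  # deg, on theta and phi
    amplitude_noise_sd: float = 0.0  # Angstrom, on Q
    jitter_sd: float = 0.03  # Angstrom, Cartesian
    random_placement: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        weights = [w for _, w in self.components]
        if not weights or any(w <= 0 for w in weights):
            raise ValueError("component weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {sum(weights)}")

    def targets(self) -> List[Tuple[float, float, float]]:
        out = []
        for spec, _ in self.components:
            if isinstance(spec, str):
                if spec not in CANONICAL_TARGETS:
                    raise ValueError(
                        f"unknown conformer class {spec!r}; "
                        f"known: {sorted(CANONICAL_TARGETS)}"
                    )
                out.append(CANONICAL_TARGETS[spec])
            else:
                out.append(tuple(float(v) for v in spec))  # type: ignore[arg-type]
        return out


def _ring_carbons(target: Tuple[float, float, float], bond: float) -> np.ndarray:
    """Ring-carbon positions: regular projected hexagon plus puckering.

    The projected radius is shrunk so the mean squared 3-D bond length
    equals ``bond`` squared; for the ideal chair (Q = bond/sqrt(6)) this
    reproduces exactly tetrahedral ring angles and equal bonds.
    """
    Q, theta, phi = target
    z = invert_pucker(Q, theta, phi)
    dz2 = float(np.mean((z - np.roll(z, -1)) ** 2))
    if dz2 >= bond * bond:
        raise GeometryError(f"puckering amplitude {Q} too large for bond {bond}")
    rho = math.sqrt(bond * bond - dz2)
    j = np.arange(6)
    ang = 2 * np.pi * j / 6
    xy = rho * np.stack([np.cos(ang), np.sin(ang)], axis=1)  # hexagon side = radius
    return np.column_stack([xy, z])


def _substituent_directions(ring_xyz: np.ndarray, j: int) -> Tuple[np.ndarray, np.ndarray]:
    """(lower, upper) unit vectors of the two out-of-ring bonds at carbon j.

    Both lie in the plane spanned by the local bond bisector and the
    perpendicular to the two ring bonds, opening by the tetrahedral
    angle; "upper" is the one with positive component along the global
    +z axis of the construction frame.
    """
    c = ring_xyz[j]
    u1 = ring_xyz[(j - 1) % 6] - c
    u2 = ring_xyz[(j + 1) % 6] - c
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    dn = np.linalg.norm(d)
    if dn < 1e-12:
        raise GeometryError("degenerate ring bonds at substituent construction")
    d /= dn
    p = np.cross(u1, u2)
    pn = np.linalg.norm(p)
    if pn < 1e-12:
        raise GeometryError("collinear ring bonds at substituent construction")
    p /= pn
    if p[2] < 0:
        p = -p
    upper = d * math.cos(_BETA) + p * math.sin(_BETA)
    lower = d * math.cos(_BETA) - p * math.sin(_BETA)
    return lower, upper


def make_ring_frame(
    target: Tuple[float, float, float],
    config: Optional[SynthesisConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Frame, RingSelection]:
    """One six-membered-ring conformer at given (Q, theta, phi).

    Carbons sit on a regular hexagon (side = C-C bond length) displaced
    out of plane by the exact puckering inverse, so the noise-free frame
    round-trips its target through :func:`~utopioid.geometry.pucker_coords`.
    CH2 carbons get two hydrogens (slot 1 = lower, slot 2 = upper);
    substituted carbons get one hydrogen plus a heavy-atom stub in the
    configured slot.  Noise (angular, amplitude, Cartesian) and random
    rigid placement are applied only when ``rng`` is given.
    """
    config = config or SynthesisConfig()
    Q, theta, phi = (float(v) for v in target)
    if Q < 0:
        raise GeometryError(f"puckering amplitude must be >= 0, got {Q}")
    if rng is not None:
        theta += rng.normal(0.0, config.angular_noise_sd)
        phi += rng.normal(0.0, config.angular_noise_sd)
        if config.amplitude_noise_sd > 0:
            Q = max(Q + rng.normal(0.0, config.amplitude_noise_sd), 0.0)

    ring_xyz = _ring_carbons((Q, theta, phi), config.bond_length)

    coords: List[np.ndarray] = [ring_xyz[j] for j in range(6)]
    elements: List[str] = ["C"] * 6
    labels: List[str] = list(RING_LABELS)
    h_map: Dict[int, List[int]] = {}

    for j in range(6):
        lower, upper = _substituent_directions(ring_xyz, j)
        carbon = ring_xyz[j]
        stub_slot = config.substituents.get(j)
        if stub_slot is None:
            # CH2: slot 1 = lower hydrogen, slot 2 = upper hydrogen
            h_map[j] = [len(coords), len(coords) + 1]
            coords.append(carbon + lower * config.ch_bond)
            elements.append("H")
            labels.append(f"H-{j + 1}'-1")
            coords.append(carbon + upper * config.ch_bond)
            elements.append("H")
            labels.append(f"H-{j + 1}'-2")
        else:
            stub_dir, h_dir = (lower, upper) if stub_slot < 0 else (upper, lower)
            h_map[j] = [len(coords)]
            coords.append(carbon + h_dir * config.ch_bond)
            elements.append("H")
            labels.append(f"H-{j + 1}'-1")
            coords.append(carbon + stub_dir * config.stub_bond)
            elements.append(config.stub_element)
            labels.append(f"{config.stub_element}-{j + 1}'")

    xyz = np.asarray(coords)
    if rng is not None:
        if config.jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, config.jitter_sd, size=xyz.shape)
        if config.random_placement:
            rot = Rotation.random(rng=rng).as_matrix()
            xyz = xyz @ rot.T + rng.normal(0.0, 5.0, size=3)

    frame = Frame(xyz, elements, labels)
    selection = RingSelection(tuple(range(6)), h_map)
    return frame, selection


def make_ensemble(config: SynthesisConfig) -> Ensemble:
    """Seeded mixture ensemble with ground-truth component labels."""
    rng = np.random.default_rng(config.seed)
    targets = config.targets()
    weights = np.array([w for _, w in config.components])
    component_of = rng.choice(len(targets), size=config.n_frames, p=weights)

    frames: List[Frame] = []
    selection: Optional[RingSelection] = None
    for comp in component_of:
        frame, sel = make_ring_frame(targets[comp], config, rng)
        frames.append(frame)
        selection = selection or sel
    names = [
        spec if isinstance(spec, str) else f"Q{spec[0]:.2f}/t{spec[1]:.0f}/p{spec[2]:.0f}"
        for spec, _ in config.components
    ]
    return Ensemble.from_frames(
        frames,
        ring=selection,
        ground_truth=component_of.astype(int),
        component_names=[str(n) for n in names],
        metadata={"seed": str(config.seed), "generator": "ring-mixture"},
    )


def _place_dihedral_chain(tau: float, bond: float = 1.54, angle: float = 111.0) -> np.ndarray:
    """Four-atom chain with bond angles ``angle`` and torsion ``tau`` deg."""
    th = math.radians(angle)
    p2 = np.zeros(3)
    p3 = np.array([bond, 0.0, 0.0])
    p1 = np.array([bond * math.cos(th), bond * math.sin(th), 0.0])
    # NeRF placement of p4 about the p2->p3 axis
    tau_r = math.radians(tau)
    bc = (p3 - p2) / bond
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(th),
            bond * math.sin(th) * math.cos(tau_r),
            bond * math.sin(th) * math.sin(tau_r),
        ]
    )
    p4 = p3 + d[0] * bc + d[1] * m + d[2] * n
    return np.stack([p1, p2, p3, p4])


def make_dihedral_ensemble(
    modes: Sequence[DihedralMode],
    n: int,
    seed: int = 0,
    force_zero: int = 0,
    random_placement: bool = True,
) -> Ensemble:
    """Ensemble of 4-atom benzylic stubs with a bimodal torsion law.

    Torsions are drawn from a mixture of wrapped normals; the sampled
    component and the torsion's sign are stored as ground truth.  No
    frame lands exactly on 0 deg unless ``force_zero`` frames (torsion
    exactly 0, appended at the end) are requested.
    """
    weights = np.array([m.weight for m in modes])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"mode weights must sum to 1, got {weights.sum()}")
    rng = np.random.default_rng(seed)
    component_of = rng.choice(len(modes), size=n, p=weights)
    taus = np.empty(n)
    for i, comp in enumerate(component_of):
        tau = rng.normal(modes[comp].mean, modes[comp].sd)
        tau = (tau + 180.0) % 360.0 - 180.0
        while tau == 0.0:  # measure-zero; keep the generator's promise
            tau = (rng.normal(modes[comp].mean, modes[comp].sd) + 180.0) % 360.0 - 180.0
        taus[i] = tau

    frames = []
    labels = ["C-1", "C-2", "C-3", "C-4"]
    truth = list(component_of.astype(int))
    for tau in taus:
        xyz = _place_dihedral_chain(float(tau))
        if random_placement:
            rot = Rotation.random(rng=rng).as_matrix()
            xyz = xyz @ rot.T + rng.normal(0.0, 5.0, size=3)
        frames.append(Frame(xyz, ["C"] * 4, list(labels)))
    for _ in range(force_zero):
        frames.append(Frame(_place_dihedral_chain(0.0), ["C"] * 4, list(labels)))
        truth.append(-1)

    return Ensemble.from_frames(
        frames,
        ground_truth=np.asarray(truth),
        component_names=[f"mode@{m.mean:+.0f}" for m in modes],
        metadata={"seed": str(seed), "generator": "dihedral-mixture"},
    )
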