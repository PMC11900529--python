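"""Plane fits, signed C-H angles, puckering coordinates, dihedrals."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from utopioid.geometry import (
    AXIAL,
    EQUATORIAL,
    Frame,
    GeometryError,
    PlaneFit,
    RingSelection,
    ch_plane_angle,
    classify_position,
    dihedral,
    fit_plane,
    invert_pucker,
    pucker_coords,
)
from conftest import ideal_chair_ring, random_rigid_transform

RING = RingSelection(tuple(range(6)))

TETRAHEDRAL = math.degrees(math.acos(-1.0 / 3.0))  # 109.4712...


def ring_frame(pts):
    return Frame(np.asarray(pts, float), ["C"] * len(pts))


class TestFitPlane:
    def test_planar_hexagon_has_zero_rms_and_perpendicular_normal(self, hexagon_frame):
        frame, ring = hexagon_frame
        fit = fit_plane(frame, ring)
        assert fit.rms == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.normal @ np.array([0.0, 0.0, 1.0])) == pytest.approx(1.0)

    def test_ideal_chair_displacements_alternate_with_equal_magnitude(self, chair_ring):
        fit = fit_plane(ring_frame(chair_ring), RING)
        disp = (chair_ring - fit.centroid) @ fit.normal
        assert np.allclose(np.abs(disp), np.abs(disp[0]), atol=1e-12)
        assert np.allclose(np.sign(disp), np.sign(disp[0]) * (-1.0) ** np.arange(6))

    def test_normal_sign_follows_ring_traversal_order(self, hexagon_frame):
        frame, ring = hexagon_frame
        # counter-clockwise traversal -> +z; reversed traversal flips it
        assert fit_plane(frame, ring).normal[2] > 0
        reversed_ring = RingSelection(tuple(reversed(ring.ring)))
        assert fit_plane(frame, reversed_ring).normal[2] < 0

    def test_rigid_transform_invariance(self, chair_ring):
        rng = np.random.default_rng(11)
        base = fit_plane(ring_frame(chair_ring), RING)
        for _ in range(100):
            rot, shift = random_rigid_transform(rng)
            moved = chair_ring @ rot.T + shift
            fit = fit_plane(ring_frame(moved), RING)
            assert fit.rms == pytest.approx(base.rms, abs=1e-8)
            assert np.allclose(fit.normal, rot @ base.normal, atol=1e-8)

    def test_agrees_with_brute_force_orientation_search(self):
        # oracle: numerically minimise sum of squared plane distances over
        # spherical normal angles
        rng = np.random.default_rng(21)
        for _ in range(50):
            pts = rng.normal(0.0, 1.0, size=(6, 3))
            frame = ring_frame(pts)
            fit = fit_plane(frame, RING)
            centred = pts - pts.mean(axis=0)

            def cost(angles):
                th, ph = angles
                n = np.array(
                    [
                        math.sin(th) * math.cos(ph),
                        math.sin(th) * math.sin(ph),
                        math.cos(th),
                    ]
                )
                return float(np.sum((centred @ n) ** 2))

            best = None
            for th0 in (0.5, 1.5, 2.5):
                for ph0 in (0.0, 2.0, 4.0):
                    res = minimize(cost, [th0, ph0], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-14})
                    if best is None or res.fun < best.fun:
                        best = res
            th, ph = best.x
            oracle_n = np.array(
                [
                    math.sin(th) * math.cos(ph),
                    math.sin(th) * math.sin(ph),
                    math.cos(th),
                ]
            )
            angle = math.acos(min(abs(float(oracle_n @ fit.normal)), 1.0))
            assert angle < 1e-4

    def test_collinear_ring_rejected(self):
        pts = np.outer(np.arange(6), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="collinear"):
            fit_plane(ring_frame(pts), RING)


class TestChPlaneAngle:
    PLANE = PlaneFit(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)

    def test_bond_along_normal_is_plus_ninety(self):
        c, h = np.zeros(3), np.array([0.0, 0.0, 1.09])
        assert ch_plane_angle(self.PLANE, c, h) == pytest.approx(90.0)

    def test_bond_in_plane_is_zero(self):
        c, h = np.zeros(3), np.array([1.09, 0.0, 0.0])
        assert ch_plane_angle(self.PLANE, c, h) == pytest.approx(0.0)

    def test_ideal_chair_axial_and_equatorial_angles(self, chair_ring):
        """Axial C-H bonds of an ideal chair are exactly perpendicular to
        the ring plane; equatorial ones tilt by the tetrahedral excess
        (109.47 - 90 = 19.47 deg)."""
        frame = ring_frame(chair_ring)
        fit = fit_plane(frame, RING)
        for j in range(6):
            up = 1.0 if j % 2 == 0 else -1.0
            axial = chair_ring[j] + 1.09 * np.array([0.0, 0.0, up])
            got = ch_plane_angle(fit, chair_ring[j], axial)
            assert abs(got) == pytest.approx(90.0, abs=1e-6)
            # equatorial: in the vertical plane through the carbon, at the
            # tetrahedral angle from axial, pointing outwards and down
            radial = chair_ring[j].copy()
            radial[2] = 0.0
            radial /= np.linalg.norm(radial)
            eq_dir = math.sin(math.radians(TETRAHEDRAL)) * radial + math.cos(
                math.radians(TETRAHEDRAL)
            ) * np.array([0.0, 0.0, up])
            equatorial = chair_ring[j] + 1.09 * eq_dir
            got_eq = ch_plane_angle(fit, chair_ring[j], equatorial)
            assert abs(got_eq) == pytest.approx(TETRAHEDRAL - 90.0, abs=1e-6)

    def test_zero_length_bond_rejected(self):
        with pytest.raises(GeometryError, match="zero-length"):
            ch_plane_angle(self.PLANE, np.zeros(3), np.zeros(3))


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (-76.98, AXIAL),  # published cluster-2 axial mean
            (-17.41, EQUATORIAL),  # published cluster-2 equatorial mean
            (45.0, AXIAL),  # boundary inclusive
            (-45.0, AXIAL),
            (44.999, EQUATORIAL),
            (90.0, AXIAL),
            (0.0, EQUATORIAL),
        ],
    )
    def test_threshold_classification(self, angle, expected):
        assert classify_position(angle) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            classify_position(95.0)


class TestPuckerCoords:
    def test_ideal_chair_theta_zero_or_pi(self, chair_ring):
        pc = pucker_coords(ring_frame(chair_ring), RING)
        assert pc.conformation == "chair"
        assert min(pc.theta, 180.0 - pc.theta) == pytest.approx(0.0, abs=1e-9)
        assert pc.q2 == pytest.approx(0.0, abs=1e-12)

    def test_ideal_boat_theta_ninety_phi_on_grid(self):
        z = invert_pucker(0.6, 90.0, 60.0)
        pts = ideal_chair_ring()
        pts[:, 2] = z
        pc = pucker_coords(ring_frame(pts), RING)
        assert pc.theta == pytest.approx(90.0, abs=1e-9)
        assert pc.phi == pytest.approx(60.0, abs=1e-9)
        assert pc.conformation == "boat"

    def test_twist_boat_phase(self):
        z = invert_pucker(0.6, 90.0, 90.0)
        pts = ideal_chair_ring()
        pts[:, 2] = z
        assert pucker_coords(ring_frame(pts), RING).conformation == "twist-boat"

    def test_planar_hexagon(self, hexagon_frame):
        frame, ring = hexagon_frame
        pc = pucker_coords(frame, ring)
        assert pc.Q == pytest.approx(0.0, abs=1e-12)
        assert pc.planar
        assert pc.conformation == "planar"

    @pytest.mark.parametrize(
        "target",
        [(0.63, 5.0, 70.0), (0.45, 90.0, 123.0), (0.3, 150.0, 300.0), (0.55, 60.0, 0.0)],
    )
    def test_round_trip_recovers_target(self, target):
        q, theta, phi = target
        pts = ideal_chair_ring()
        pts[:, 2] = invert_pucker(q, theta, phi)
        pc = pucker_coords(ring_frame(pts), RING)
        assert pc.Q == pytest.approx(q, abs=1e-6)
        assert pc.theta == pytest.approx(theta, abs=1e-6)
        assert pc.phi == pytest.approx(phi, abs=1e-6)

    def test_chair_displacements_alternate_in_sign(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = rng.uniform(0.3, 0.7)
            theta = rng.uniform(0.0, 20.0)
            pts = ideal_chair_ring()
            pts[:, 2] = invert_pucker(q, theta, rng.uniform(0, 360))
            frame = ring_frame(pts)
            pc = pucker_coords(frame, RING)
            if pc.conformation != "chair":
                continue
            fit = fit_plane(frame, RING)
            disp = (pts - fit.centroid) @ fit.normal
            signs = np.sign(disp)
            assert np.all(signs == signs[0] * (-1.0) ** np.arange(6))


class TestDihedral:
    def test_syn_planar_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_anti_planar_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(
            180.0
        )

    @pytest.mark.parametrize("tau", [60.0, -60.0, 90.0, -90.0, 175.0])
    def test_staggered_chain_matches_two_plane_normal_oracle(self, tau):
        from utopioid.synth import _place_dihedral_chain

        pts = _place_dihedral_chain(tau)
        got = dihedral(*pts)
        assert got == pytest.approx(tau, abs=1e-9)
        # independent oracle: unsigned angle between the two bond planes,
        # signed by the scalar triple product
        b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
        unsigned = math.degrees(math.acos(np.clip(cosang, -1, 1)))
        sign = math.copysign(1.0, float(np.cross(n1, n2) @ b2))
        assert got == pytest.approx(sign * unsigned, abs=1e-9)

    def test_rigid_transform_invariance(self):
        from utopioid.synth import _place_dihedral_chain

        rng = np.random.default_rng(9)
        pts = _place_dihedral_chain(47.0)
        for _ in range(25):
            rot, shift = random_rigid_transform(rng)
            moved = pts @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(47.0, abs=1e-8)

    def test_collinear_middle_triple_rejected(self):
        with pytest.raises(GeometryError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])
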