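"""Alignment, RMSD matrices, dihedral-sign and conformer clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import random_rigid_transform
from utopioid.ensemble import (
    Ensemble,
    align_ensemble,
    cluster_angle_stats,
    cluster_conformers,
    cluster_dihedral,
    kabsch_align,
    rmsd_matrix,
)
from utopioid.geometry import Frame
from utopioid.synth import (
    CANONICAL_TARGETS,
    DihedralMode,
    SynthesisConfig,
    make_dihedral_ensemble,
    make_ensemble,
    make_ring_frame,
)


def small_mixture(n=300, seed=7, noise=6.0):
    return make_ensemble(
        SynthesisConfig(
            components=[("chair", 0.85), ("chair-flipped", 0.11), ("boat", 0.04)],
            n_frames=n,
            seed=seed,
            angular_noise_sd=noise,
        )
    )


class TestKabschAlign:
    def test_self_alignment_is_zero_rmsd(self):
        frame, ring = make_ring_frame(CANONICAL_TARGETS["chair"])
        _, rmsd = kabsch_align(frame, frame, list(range(frame.n_atoms)))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_a_known_rigid_transform(self):
        frame, _ = make_ring_frame(CANONICAL_TARGETS["boat"])
        rng = np.random.default_rng(13)
        rot, shift = random_rigid_transform(rng)
        moved = Frame(frame.coords @ rot.T + shift, frame.elements, frame.labels)
        aligned, rmsd = kabsch_align(frame, moved, list(range(frame.n_atoms)))
        assert rmsd < 1e-9
        assert np.allclose(aligned.coords, frame.coords, atol=1e-9)

    def test_reflection_is_not_available(self):
        """A mirrored frame cannot reach zero RMSD; the result matches an
        independent proper-rotation optimiser (scipy align_vectors)."""
        from scipy.spatial.transform import Rotation

        frame, _ = make_ring_frame(CANONICAL_TARGETS["chair"])
        mirrored = Frame(
            frame.coords * np.array([1.0, 1.0, -1.0]), frame.elements, frame.labels
        )
        sel = list(range(frame.n_atoms))
        _, rmsd = kabsch_align(frame, mirrored, sel)
        assert rmsd > 0.1
        a = frame.coords - frame.coords.mean(axis=0)
        b = mirrored.coords - mirrored.coords.mean(axis=0)
        rot, rssd = Rotation.align_vectors(a, b)
        oracle = rssd / np.sqrt(len(sel))
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_too_few_selected_atoms_rejected(self):
        frame, _ = make_ring_frame(CANONICAL_TARGETS["chair"])
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_align(frame, frame, [0, 1])


class TestRmsdMatrix:
    def test_duplicate_frames_give_zero_entries(self):
        ens = small_mixture(n=5, seed=3)
        dup = Ensemble(
            np.concatenate([ens.coords, ens.coords[:1]]),
            ens.elements,
            ens.labels,
            ens.ring,
        )
        dm = rmsd_matrix(dup, list(range(dup.n_atoms)))
        assert dm[0, 5] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_zero_diagonal_nonnegative(self):
        ens = small_mixture(n=20, seed=5)
        dm = rmsd_matrix(ens)
        assert np.allclose(dm, dm.T, atol=1e-12)
        assert np.allclose(np.diag(dm), 0.0)
        assert np.all(dm >= 0)

    def test_two_frame_toy_matches_direct_formula(self):
        # 3-atom toy, pre-centred and pre-rotated: RMSD by hand
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        b = a + np.array([0.0, 0.0, 1.0]) * np.array([[1.0], [0.0], [0.0]])
        ens = Ensemble(np.stack([a, b]), ["C"] * 3)
        dm = rmsd_matrix(ens, [0, 1, 2], superpose=False)
        diff = a - b
        expected = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
        assert dm[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_frame_permutation_permutes_matrix(self):
        ens = small_mixture(n=8, seed=8)
        dm = rmsd_matrix(ens, list(range(ens.n_atoms)))
        perm = np.array([3, 1, 4, 0, 2, 7, 6, 5])
        permuted = Ensemble(ens.coords[perm], ens.elements, ens.labels, ens.ring)
        dmp = rmsd_matrix(permuted, list(range(ens.n_atoms)))
        assert np.allclose(dmp, dm[np.ix_(perm, perm)], atol=1e-9)

    def test_matches_per_pair_kabsch_recomputation(self):
        """Batched closed-form matrix equals brute-force pairwise Kabsch."""
        ens = small_mixture(n=10, seed=11)
        sel = ens.bonded_selection()
        dm = rmsd_matrix(ens, sel)
        for i in range(10):
            for j in range(i + 1, 10):
                _, rmsd = kabsch_align(ens.frame(i), ens.frame(j), sel)
                assert dm[i, j] == pytest.approx(rmsd, abs=1e-9)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Ensemble(np.empty((0, 4, 3)), ["C"] * 4)


class TestClusterDihedral:
    LABELS = ["C-1", "C-2", "C-3", "C-4"]

    def test_bimodal_mixture_fractions_within_three_se(self):
        ens = make_dihedral_ensemble(
            [DihedralMode(85.0, 20.0, 0.6), DihedralMode(-85.0, 20.0, 0.4)],
            2000,
            seed=17,
        )
        report = cluster_dihedral(ens, self.LABELS)
        se = np.sqrt(0.6 * 0.4 / 2000)
        assert abs(report.fractions[0] - 0.6) <= 3 * se
        assert report.fractions[0] + report.fractions[1] == pytest.approx(1.0, abs=1e-12)

    def test_all_positive_ensemble_leaves_negative_cluster_empty(self):
        ens = make_dihedral_ensemble([DihedralMode(85.0, 5.0, 1.0)], 50, seed=2)
        report = cluster_dihedral(ens, self.LABELS)
        assert report.counts == (50, 0)

    def test_exact_cutoff_frame_goes_positive(self):
        ens = make_dihedral_ensemble(
            [DihedralMode(85.0, 5.0, 1.0)], 3, seed=2, force_zero=1
        )
        report = cluster_dihedral(ens, self.LABELS)
        assert report.assignments[-1] == 1

    def test_fraction_recovery_over_repeated_seeds(self):
        """Mixture-fraction recovery within 3 binomial SE, 20 repetitions."""
        w = 0.7
        n = 400
        se = np.sqrt(w * (1 - w) / n)
        failures = 0
        for rep in range(20):
            ens = make_dihedral_ensemble(
                [DihedralMode(85.0, 25.0, w), DihedralMode(-85.0, 25.0, 1 - w)],
                n,
                seed=100 + rep,
            )
            report = cluster_dihedral(ens, self.LABELS)
            if abs(report.fractions[0] - w) > 3 * se:
                failures += 1
        assert failures == 0

    def test_wrong_label_count_rejected(self):
        ens = make_dihedral_ensemble([DihedralMode(85, 5, 1.0)], 3, seed=1)
        with pytest.raises(ValueError, match="4 atom labels"):
            cluster_dihedral(ens, ["C-1", "C-2"])


class TestClusterConformers:
    def test_three_component_mixture_recovered(self):
        ens = small_mixture(n=300, seed=7)
        report = cluster_conformers(ens)
        assert len(report.clusters) == 3
        ari = adjusted_rand_score(ens.ground_truth, report.frame_labels)
        assert ari >= 0.95
        fractions = sorted((c.fraction for c in report.clusters), reverse=True)
        for got, w in zip(fractions, (0.85, 0.11, 0.04)):
            se = np.sqrt(w * (1 - w) / ens.n_frames)
            assert abs(got - w) <= 3 * se

    def test_dominant_cluster_is_a_chair(self):
        ens = small_mixture(n=200, seed=23)
        report = cluster_conformers(ens)
        assert report.clusters[0].conformation == "chair"

    def test_single_conformer_collapses_to_one_cluster(self):
        ens = make_ensemble(
            SynthesisConfig(
                components=[("chair", 1.0)],
                n_frames=60,
                seed=4,
                angular_noise_sd=3.0,
                jitter_sd=0.01,
            )
        )
        report = cluster_conformers(ens, k_init=14)
        assert len(report.clusters) == 1
        assert report.clusters[0].fraction == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        ens = small_mixture(n=120, seed=31)
        report = cluster_conformers(ens)
        assert sum(c.fraction for c in report.clusters) == pytest.approx(1.0, abs=1e-12)
        assert sum(c.count for c in report.clusters) == ens.n_frames

    def test_k_init_larger_than_ensemble_rejected(self):
        ens = small_mixture(n=10, seed=1)
        with pytest.raises(ValueError, match="k_init"):
            cluster_conformers(ens, k_init=11)

    def test_end_to_end_determinism_byte_identical_reports(self):
        a = cluster_conformers(small_mixture(n=150, seed=19)).to_json()
        b = cluster_conformers(small_mixture(n=150, seed=19)).to_json()
        assert a == b


class TestClusterAngleStats:
    def test_identical_frames_have_zero_sd(self):
        frame, ring = make_ring_frame(CANONICAL_TARGETS["chair"])
        ens = Ensemble.from_frames([frame] * 5, ring=ring)
        stats, consensus = cluster_angle_stats(ens, range(5))
        assert consensus == "chair"
        assert all(s.sd == 0.0 for s in stats)

    def test_chair_template_reproduces_published_axial_equatorial_pattern(self):
        """The dominant-chair partition: single protons on the two
        substituted carbons plus one proton per CH2 are axial (6 total),
        the remaining four CH2 protons equatorial."""
        ens = make_ensemble(
            SynthesisConfig(components=[("chair", 1.0)], n_frames=40, seed=6)
        )
        stats, consensus = cluster_angle_stats(ens, range(ens.n_frames))
        assert consensus == "chair"
        calls = {(s.carbon_label, s.hydrogen_slot): s.position for s in stats}
        expected_axial = {
            ("C-1'", 1),
            ("C-2'", 1),
            ("C-3'", 2),
            ("C-4'", 1),
            ("C-5'", 2),
            ("C-6'", 1),
        }
        axial = {k for k, v in calls.items() if v == "axial"}
        assert axial == expected_axial
        assert len(calls) - len(axial) == 4

    def test_flipped_chair_swaps_every_call(self):
        cfg = dict(n_frames=30, seed=8)
        up = make_ensemble(SynthesisConfig(components=[("chair", 1.0)], **cfg))
        down = make_ensemble(
            SynthesisConfig(components=[("chair-flipped", 1.0)], **cfg)
        )
        stats_up, _ = cluster_angle_stats(up, range(up.n_frames))
        stats_down, _ = cluster_angle_stats(down, range(down.n_frames))
        for su, sd in zip(stats_up, stats_down):
            assert (su.carbon_label, su.hydrogen_slot) == (
                sd.carbon_label,
                sd.hydrogen_slot,
            )
            assert su.position != sd.position

    def test_empty_subset_rejected(self):
        frame, ring = make_ring_frame(CANONICAL_TARGETS["chair"])
        ens = Ensemble.from_frames([frame], ring=ring)
        with pytest.raises(ValueError, match="empty"):
            cluster_angle_stats(ens, [])


class TestAlignEnsemble:
    def test_alignment_removes_rigid_placement(self):
        ens = small_mixture(n=30, seed=44)
        aligned = align_ensemble(ens, list(ens.ring.ring))
        # after alignment the ring centroids nearly coincide with frame 0's
        ref = aligned.coords[0][list(ens.ring.ring)].mean(axis=0)
        for k in range(aligned.n_frames):
            c = aligned.coords[k][list(ens.ring.ring)].mean(axis=0)
            assert np.linalg.norm(c - ref) < 0.25
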