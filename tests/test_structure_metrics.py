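"""Backbone RMSD, crossing angles, contact counts, and trajectory summaries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgkit.structure_metrics import (
    DimerFrame,
    DimerReference,
    PeptideBackbone,
    backbone_rmsd,
    crossing_angle,
    dimer_deviation_summary,
    in_acceptable_region,
    interpeptide_contacts,
    kabsch_superpose,
    map_atomistic_to_cg_backbone,
    motif_align,
    principal_axis,
    replica_summary_table,
)
from cgkit.synthetic_fixtures import ideal_helix, make_crossed_dimer


def brute_force_min_rmsd(mobile, ref, rng, n_global=20_000, n_refine=4000):
    """Oracle: global random-rotation scan plus shrinking local perturbations."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)

    def rmsds(rots):
        moved = np.einsum("rij,nj->rni", rots.as_matrix(), mc)
        return np.sqrt(np.mean(np.sum((moved - rc) ** 2, axis=2), axis=1))

    cand = Rotation.random(n_global, rng=rng)
    vals = rmsds(cand)
    best, best_val = cand[int(np.argmin(vals))], float(vals.min())
    for sigma in (0.1, 0.01, 0.001, 1e-4):
        pert = Rotation.from_rotvec(rng.normal(0, sigma, (n_refine, 3)))
        cand = pert * best
        vals = rmsds(cand)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best, best_val = cand[i], float(vals[i])
    return best_val


def rigid_copy(frame, rot, shift):
    R = rot.as_matrix()
    peps = tuple(
        PeptideBackbone((R @ p.coords.T).T + shift, p.resids, p.peptide_id)
        for p in frame.peptides)
    return DimerFrame(peptides=peps, box=frame.box)


PDB_HELIX = "\n".join(
    [
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1",
    ]
    + [
        f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
        f"{4.7:8.3f}{1.5 * i:8.3f}{0.0:8.3f}  1.00  0.00           C"
        for i in range(20)
    ]
    + ["TER"]
    + [
        f"ATOM  {i + 21:5d}  CA  ALA B{i + 1:4d}    "
        f"{9.0:8.3f}{1.5 * i:8.3f}{0.0:8.3f}  1.00  0.00           C"
        for i in range(20)
    ]
    + ["TER", "END"]
) + "\n"


class TestBackboneMapping:
    def test_one_bead_per_residue(self):
        bb = map_atomistic_to_cg_backbone(PDB_HELIX, "A")
        assert len(bb) == 20
        assert bb.coords[0][0] == pytest.approx(0.47)  # Angstrom -> nm

    def test_two_chains_get_distinct_ids(self):
        a = map_atomistic_to_cg_backbone(PDB_HELIX, "A")
        b = map_atomistic_to_cg_backbone(PDB_HELIX, "B")
        assert a.peptide_id != b.peptide_id

    def test_missing_ca_names_residue(self):
        broken = PDB_HELIX.replace("  CA  ALA A   3", "  CB  ALA A   3")
        with pytest.raises(ValueError, match="3"):
            map_atomistic_to_cg_backbone(broken, "A")

    def test_unknown_chain_errors(self):
        with pytest.raises(ValueError, match="chain"):
            map_atomistic_to_cg_backbone(PDB_HELIX, "Z")


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = ideal_helix(12).coords
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self):
        pts = ideal_helix(12).coords
        rot = Rotation.from_euler("z", 37, degrees=True)
        moved = (rot.as_matrix() @ pts.T).T + [0.3, -1.0, 2.0]
        R, t, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(R, rot.inv().as_matrix(), atol=1e-8)

    def test_matches_brute_force_on_toy_points(self):
        """Optimal RMSD of a noisy 3-point fit equals a random-rotation scan."""
        rng = np.random.default_rng(5)
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.2, 0]])
        b = a + rng.normal(0, 0.1, a.shape)
        _, _, rmsd = kabsch_superpose(a, b)
        brute = brute_force_min_rmsd(a, b, rng)
        assert rmsd <= brute + 1e-12
        assert abs(rmsd - brute) < 1e-3

    def test_reflection_case_returns_proper_rotation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 2] *= -1  # mirrored target
        R, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_counts_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestBackboneRmsd:
    @pytest.fixture()
    def dimer_and_ref(self):
        frame = make_crossed_dimer(40.0)
        ref = DimerReference.from_frame(frame, ((1, 26), (1, 26)))
        return frame, ref

    def test_identical_frame_is_zero(self, dimer_and_ref):
        frame, ref = dimer_and_ref
        assert backbone_rmsd(frame, ref) < 1e-10

    def test_rigid_copy_is_zero(self, dimer_and_ref):
        frame, ref = dimer_and_ref
        moved = rigid_copy(frame, Rotation.from_euler("xyz", [10, 80, -30], degrees=True),
                           np.array([1.0, 2.0, 3.0]))
        assert backbone_rmsd(moved, ref) < 1e-10

    def test_chain_swap_resolved_by_pairing_minimum(self, dimer_and_ref):
        frame, ref = dimer_and_ref
        swapped = DimerFrame(peptides=(frame.peptides[1], frame.peptides[0]))
        assert backbone_rmsd(swapped, ref) < 1e-10

    def test_translated_peptide_matches_brute_force(self, dimer_and_ref):
        """Joint-fit RMSD after moving one peptide equals a rotation-grid scan."""
        frame, ref = dimer_and_ref
        p1, p2 = frame.peptides
        moved = DimerFrame(peptides=(
            p1, PeptideBackbone(p2.coords + [0.0, 0.0, 1.0], p2.resids, 2)))
        got = backbone_rmsd(moved, ref)
        mob = np.vstack([moved.peptides[0].coords, moved.peptides[1].coords])
        tgt = np.vstack([ref.peptides[0].coords, ref.peptides[1].coords])
        brute = brute_force_min_rmsd(mob, tgt, np.random.default_rng(0))
        assert got <= brute + 1e-12
        assert abs(got - brute) < 1e-3

    def test_never_exceeds_unsuperposed_rmsd(self, dimer_and_ref):
        frame, ref = dimer_and_ref
        rng = np.random.default_rng(1)
        for _ in range(20):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(0, 2, 3)
            moved = rigid_copy(frame, rot, shift)
            noisy = DimerFrame(peptides=tuple(
                PeptideBackbone(p.coords + rng.normal(0, 0.1, p.coords.shape),
                                p.resids, p.peptide_id)
                for p in moved.peptides))
            mob = np.vstack([p.coords for p in noisy.peptides])
            tgt = np.vstack([p.coords for p in ref.peptides])
            raw = np.sqrt(np.mean(np.sum((mob - tgt) ** 2, axis=1)))
            assert backbone_rmsd(noisy, ref) <= raw + 1e-12


class TestPrincipalAxisAndAngle:
    def test_beads_on_z_axis(self):
        bb = PeptideBackbone(np.column_stack([np.zeros(5), np.zeros(5),
                                              np.arange(5.0)]),
                             np.arange(1, 6))
        np.testing.assert_allclose(principal_axis(bb), [0, 0, 1], atol=1e-12)

    def test_ideal_helix_axis_recovery(self):
        bb = ideal_helix(26, axis=(0, 0, 1))
        np.testing.assert_allclose(principal_axis(bb), [0, 0, 1], atol=1e-6)

    def test_sign_points_first_to_last(self):
        bb = PeptideBackbone(np.column_stack([np.arange(5.0)[::-1], np.zeros(5),
                                              np.zeros(5)]),
                             np.arange(1, 6))
        np.testing.assert_allclose(principal_axis(bb), [-1, 0, 0], atol=1e-12)

    def test_coincident_beads_error(self):
        bb = PeptideBackbone(np.zeros((4, 3)), np.arange(1, 5))
        with pytest.raises(ValueError, match="spread"):
            principal_axis(bb)

    @pytest.mark.parametrize("angle", [0.0, 25.0, 40.0, 90.0])
    def test_constructed_crossing_angle_recovered(self, angle):
        frame = make_crossed_dimer(angle)
        assert crossing_angle(frame) == pytest.approx(angle, abs=1e-6)

    def test_symmetric_and_bounded(self):
        frame = make_crossed_dimer(63.0)
        swapped = DimerFrame(peptides=(frame.peptides[1], frame.peptides[0]))
        assert crossing_angle(frame) == pytest.approx(crossing_angle(swapped))
        rng = np.random.default_rng(2)
        for _ in range(20):
            moved = rigid_copy(frame, Rotation.random(rng=rng), rng.normal(0, 3, 3))
            theta = crossing_angle(moved)
            assert 0.0 <= theta <= 90.0
            assert theta == pytest.approx(63.0, abs=1e-6)

    def test_antiparallel_is_zero(self):
        p1 = ideal_helix(20, axis=(0, 0, 1), peptide_id=1)
        p2 = ideal_helix(20, axis=(0, 0, -1), origin=(1.0, 0, 0), peptide_id=2)
        assert crossing_angle(DimerFrame(peptides=(p1, p2))) == pytest.approx(0.0, abs=1e-6)


class TestContacts:
    def test_far_apart_is_zero(self):
        p1 = ideal_helix(10, peptide_id=1)
        p2 = ideal_helix(10, origin=(5.0, 0, 0), peptide_id=2)
        assert interpeptide_contacts(DimerFrame(peptides=(p1, p2))) == 0

    def test_constructed_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, 2)
            box = rng.uniform(3.0, 8.0, 3)
            c1 = rng.uniform(0, box, (n1, 3))
            c2 = rng.uniform(0, box, (n2, 3))
            frame = DimerFrame(peptides=(
                PeptideBackbone(c1, np.arange(1, n1 + 1), 1),
                PeptideBackbone(c2, np.arange(1, n2 + 1), 2)), box=box)
            brute = 0
            for i in range(n1):
                for j in range(n2):
                    d = c1[i] - c2[j]
                    d -= box * np.round(d / box)
                    if np.linalg.norm(d) <= 0.8:
                        brute += 1
            assert interpeptide_contacts(frame, 0.8) == brute

    def test_closed_boundary(self):
        p1 = PeptideBackbone(np.array([[0.0, 0, 0], [0, 0, 1], [0, 0, 2]]),
                             np.arange(1, 4), 1)
        p2 = PeptideBackbone(np.array([[0.8, 0, 0], [5, 5, 1], [5, 5, 2]]),
                             np.arange(1, 4), 2)
        assert interpeptide_contacts(DimerFrame(peptides=(p1, p2)), 0.8) == 1


class TestSummary:
    @pytest.fixture()
    def ref(self):
        return DimerReference.from_frame(make_crossed_dimer(40.0), ((1, 26), (1, 26)))

    def test_reference_trajectory_gives_zeros(self, ref):
        frames = [make_crossed_dimer(40.0)] * 6
        s = dimer_deviation_summary(frames, ref, window_frac=0.5)
        assert s.mean_rmsd < 1e-10
        assert s.mean_abs_dangle < 1e-6
        assert s.mean_dcontacts == 0
        assert s.n_frames == 3

    def test_two_conformation_average_is_hand_mean(self, ref):
        f40 = make_crossed_dimer(40.0)
        f50 = make_crossed_dimer(50.0)
        s = dimer_deviation_summary([f40, f50] * 4, ref, window_frac=1.0)
        # |40-40| = 0 and |50-40| = 10, mean 5
        assert s.mean_abs_dangle == pytest.approx(5.0, abs=1e-6)

    def test_window_uses_trailing_frames_only(self, ref):
        frames = [make_crossed_dimer(80.0)] * 5 + [make_crossed_dimer(40.0)] * 5
        s = dimer_deviation_summary(frames, ref, window_frac=0.5)
        assert s.n_frames == 5
        assert s.mean_abs_dangle < 1e-6

    def test_acceptance_region_threshold(self, ref):
        good = dimer_deviation_summary([make_crossed_dimer(44.0)], ref, 1.0)
        bad = dimer_deviation_summary([make_crossed_dimer(75.0)], ref, 1.0)
        assert in_acceptable_region(good)
        assert not in_acceptable_region(bad)

    def test_replica_table_has_mean_row(self, ref):
        reps = [[make_crossed_dimer(40.0)] * 4, [make_crossed_dimer(50.0)] * 4]
        df = replica_summary_table(reps, ref, window_frac=0.5)
        assert list(df["replica"]) == ["1", "2", "mean"]
        assert df["mean_abs_dangle"].iloc[-1] == pytest.approx(5.0, abs=1e-6)

    def test_motif_alignment_transforms_whole_dimer(self):
        frame = make_crossed_dimer(40.0)
        ref = DimerReference.from_frame(frame, ((1, 26), (1, 26)),
                                        motif_range=(5, 15))
        moved = rigid_copy(frame, Rotation.from_euler("y", 25, degrees=True),
                           np.array([1.0, 0, 0]))
        aligned, rmsd = motif_align(moved, ref)
        assert rmsd < 1e-10
        np.testing.assert_allclose(aligned.peptides[1].coords,
                                   frame.peptides[1].coords, atol=1e-8)
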