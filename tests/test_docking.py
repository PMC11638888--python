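"""Restraint extraction, surrogate scoring and the staged docking funnel."""

import dataclasses

import numpy as np
import pytest

from pendock import docking
from pendock.docking import (
    ActivePassiveSpec,
    DockingProtocol,
    Restraint,
    cluster_poses,
    dock,
    extract_ca_restraints,
    ligand_rmsd,
    score_pose,
    select_final_model,
)
from pendock.structure import Structure


def two_ca_reference(distance=5.0):
    return Structure.from_atoms([
        ("R", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
        ("L", 2, "GLY", "CA", "C", (distance, 0.0, 0.0)),
    ])


class TestRestraints:
    def test_target_is_reference_distance(self):
        ref = two_ca_reference(5.0)
        (r,) = extract_ca_restraints(ref, [(("R", 1), ("L", 2))])
        assert r.target == pytest.approx(5.0)
        assert r.tolerance == 0.0

    def test_missing_residue_named(self):
        ref = two_ca_reference()
        with pytest.raises(KeyError, match="R:9"):
            extract_ca_restraints(ref, [(("R", 9), ("L", 2))])

    def test_invalid_restraint_values(self):
        with pytest.raises(ValueError):
            Restraint(("R", 1), ("L", 2), target=-1.0)
        with pytest.raises(ValueError):
            Restraint(("R", 1), ("L", 2), target=5.0, tolerance=-0.1)

    @pytest.mark.parametrize("tolerance", [0.0, 0.3])
    def test_self_consistency_zero_violation(self, toy_complex, tolerance):
        reference = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        pairs = [(r.receptor, r.ligand) for r in toy_complex.restraints]
        restraints = extract_ca_restraints(reference, pairs, tolerance=tolerance)
        e = score_pose(toy_complex.receptor, toy_complex.ligand,
                       restraints=restraints)
        assert e.restraint == 0.0

    def test_active_passive_overlap_rejected(self):
        with pytest.raises(ValueError):
            ActivePassiveSpec(active_receptor=[("R", 1)], passive_receptor=[("R", 1)])


class TestScoring:
    def test_clash_term_quadratic(self):
        rec = Structure.from_atoms([("R", 1, "GLY", "CA", "C", (0, 0, 0))])
        lig = Structure.from_atoms([("L", 1, "GLY", "CA", "C", (1.0, 0, 0))])
        e = score_pose(rec, lig)
        assert e.clash == pytest.approx((2.5 - 1.0) ** 2)
        assert e.contact == -1.0

    def test_restraint_grows_quadratically_beyond_target(self):
        rec = Structure.from_atoms([("R", 1, "GLY", "CA", "C", (0, 0, 0))])
        lig = Structure.from_atoms([("L", 2, "GLY", "CA", "C", (5.0, 0, 0))])
        restraints = [Restraint(("R", 1), ("L", 2), target=5.0)]
        for shift in (2.0, 6.0, 10.0):
            e = score_pose(rec, lig, (np.eye(3), np.array([shift, 0, 0])),
                           restraints)
            assert e.restraint == pytest.approx(shift**2)

    def test_flat_bottom_tolerance(self):
        rec = Structure.from_atoms([("R", 1, "GLY", "CA", "C", (0, 0, 0))])
        lig = Structure.from_atoms([("L", 2, "GLY", "CA", "C", (5.0, 0, 0))])
        restraints = [Restraint(("R", 1), ("L", 2), target=5.0, tolerance=0.3)]
        e = score_pose(rec, lig, (np.eye(3), np.array([0.25, 0, 0])), restraints)
        assert e.restraint == 0.0
        e = score_pose(rec, lig, (np.eye(3), np.array([0.5, 0, 0])), restraints)
        assert e.restraint == pytest.approx(0.2**2)

    def test_total_is_weighted_sum(self, toy_complex):
        e = score_pose(toy_complex.receptor, toy_complex.ligand,
                       restraints=toy_complex.restraints, weights=(2.0, 1.5, 0.2))
        assert e.total == pytest.approx(2.0 * e.restraint + 1.5 * e.clash
                                        + 0.2 * e.contact)

    def test_energy_invariant_under_shared_rigid_transform(self, toy_complex):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [33, -12, 58], degrees=True).as_matrix()
        trans = np.array([5.0, -7.0, 2.0])
        base = score_pose(toy_complex.receptor, toy_complex.ligand,
                          restraints=toy_complex.restraints, spec=toy_complex.spec)
        moved = score_pose(toy_complex.receptor.transformed(rot, trans),
                           toy_complex.ligand.transformed(rot, trans),
                           restraints=[dataclasses.replace(
                               r, target=r.target) for r in toy_complex.restraints],
                           spec=toy_complex.spec)
        assert moved.restraint == pytest.approx(base.restraint, abs=1e-9)
        assert moved.clash == pytest.approx(base.clash, abs=1e-9)
        assert moved.contact == base.contact

    def test_nonfinite_transform_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            score_pose(toy_complex.receptor, toy_complex.ligand,
                       (np.full((3, 3), np.nan), np.zeros(3)))


class TestFunnel:
    def test_degenerate_single_pose_protocol(self, toy_complex):
        protocol = DockingProtocol(stage="A", n_generated=1, n_scored_kept=1,
                                   n_clustered=1, seed=4)
        poses, clustering = dock(toy_complex.receptor, toy_complex.ligand,
                                 toy_complex.restraints, toy_complex.spec, protocol)
        assert len(poses) == 1
        assert poses[0].rank == 1
        assert len(clustering.clusters) == 1

    def test_stage_b_zero_perturbation_is_fixed_point(self, toy_complex):
        protocol = DockingProtocol(stage="B", n_generated=3, n_scored_kept=3,
                                   n_clustered=3, seed=6,
                                   perturb_rotation_deg=0.0, perturb_translation=0.0)
        poses, clustering = dock(toy_complex.receptor, toy_complex.ligand,
                                 toy_complex.restraints, toy_complex.spec, protocol,
                                 seed_pose=toy_complex.truth_transform)
        best = select_final_model(poses, clustering)
        assert np.allclose(best.rotation, np.eye(3))
        assert np.allclose(best.translation, np.zeros(3))
        assert best.energy.restraint == 0.0

    def test_stage_b_requires_seed_pose(self, toy_complex):
        protocol = DockingProtocol(stage="B", n_generated=1, n_scored_kept=1,
                                   n_clustered=1)
        with pytest.raises(ValueError):
            dock(toy_complex.receptor, toy_complex.ligand, toy_complex.restraints,
                 toy_complex.spec, protocol)

    def test_ranking_is_a_permutation_and_sorted(self, toy_complex):
        protocol = DockingProtocol(stage="A", n_generated=12, n_scored_kept=12,
                                   n_clustered=5, seed=2, minimize_maxfev=40)
        poses, _ = dock(toy_complex.receptor, toy_complex.ligand,
                        toy_complex.restraints, toy_complex.spec, protocol)
        ranks = [p.rank for p in poses]
        assert sorted(ranks) == list(range(1, 13))
        totals = [p.energy.total for p in poses]
        assert totals == sorted(totals)

    def test_deterministic_given_seed(self, toy_complex):
        protocol = DockingProtocol(stage="A", n_generated=4, n_scored_kept=4,
                                   n_clustered=2, seed=9, minimize_maxfev=30)
        a, _ = dock(toy_complex.receptor, toy_complex.ligand,
                    toy_complex.restraints, toy_complex.spec, protocol)
        b, _ = dock(toy_complex.receptor, toy_complex.ligand,
                    toy_complex.restraints, toy_complex.spec, protocol)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.rotation, pb.rotation)
            assert np.array_equal(pa.translation, pb.translation)

    def test_funnel_ordering_validated(self):
        with pytest.raises(ValueError):
            DockingProtocol(n_generated=10, n_scored_kept=20, n_clustered=5)

    def test_single_run_recovers_planted_pose(self, toy_complex):
        protocol = DockingProtocol(stage="A", n_generated=60, n_scored_kept=20,
                                   n_clustered=10, seed=3)
        poses, clustering = dock(toy_complex.receptor, toy_complex.ligand,
                                 toy_complex.restraints, toy_complex.spec, protocol)
        final = select_final_model(poses, clustering)
        assert ligand_rmsd(final, toy_complex.truth_transform,
                           toy_complex.ligand) <= 2.0


class TestPoseClusteringAndSelection:
    def make_pose(self, translation, energy_total):
        e = docking.EnergyBreakdown(restraint=0.0, clash=0.0,
                                    contact=energy_total / 0.1)
        return docking.DockedPose(np.eye(3), np.asarray(translation, float), e)

    def test_identical_poses_one_cluster(self, toy_complex):
        poses = [self.make_pose([0, 0, 0], -1.0) for _ in range(5)]
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        assert len(res.clusters) == 1
        assert all(p.cluster_id == 0 for p in poses)

    def test_two_planted_pose_families(self, toy_complex):
        poses = ([self.make_pose([0, 0, 0], -1.0) for _ in range(6)]
                 + [self.make_pose([30.0, 0, 0], -1.0) for _ in range(4)])
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        assert [c.size for c in res.clusters] == [6, 4]

    def test_singleton(self, toy_complex):
        poses = [self.make_pose([0, 0, 0], -2.0)]
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        assert [c.size for c in res.clusters] == [1]

    def test_best_energy_in_most_populated_cluster(self, toy_complex):
        poses = ([self.make_pose([0, 0, 0], -10.0),
                  self.make_pose([0.5, 0, 0], -8.0)]
                 + [self.make_pose([30, 0, 0], -12.0),
                    self.make_pose([30.5, 0, 0], -9.0)])
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        final = select_final_model(poses, res)
        # equal-size clusters tie: the -12 pose wins
        assert final.energy.total == pytest.approx(-12.0)

    def test_single_cluster_lowest_energy(self, toy_complex):
        poses = [self.make_pose([d, 0, 0], e)
                 for d, e in ((0, -3.0), (0.4, -7.0), (0.8, -5.0))]
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        final = select_final_model(poses, res)
        assert final.energy.total == pytest.approx(-7.0)

    def test_empty_selection_errors(self, toy_complex):
        poses = [self.make_pose([0, 0, 0], -1.0)]
        res = cluster_poses(poses, toy_complex.ligand, cutoff=5.0)
        empty = dataclasses.replace(res, clusters=[])
        with pytest.raises(ValueError):
            select_final_model(poses, empty)
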