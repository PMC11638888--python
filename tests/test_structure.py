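"""Structure container, SASA, superposition and RMSD primitives."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pendock.structure import (
    Structure,
    ca_rmsd,
    coords_rmsd,
    kabsch_superpose,
    parse_structure,
    read_models,
    shrake_rupley_sasa,
    sphere_points,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def single_atom(element="C", resname="ALA", name="CA", xyz=(0.0, 0.0, 0.0)):
    return Structure.from_atoms([("A", 1, resname, name, element, xyz)])


class TestParsingAndWriting:
    def test_minimal_pdb(self):
        s = parse_structure(MINIMAL_PDB, fmt="pdb")
        assert len(s) == 3
        assert s.atom_coord("A", 1, "CA")[0] == pytest.approx(1.458)
        assert list(s.atname) == ["N", "CA", "C"]

    def test_round_trip(self, toy_complex, tmp_path):
        path = tmp_path / "receptor.pdb"
        write_pdb(toy_complex.receptor, path)
        back = parse_structure(path)
        assert len(back) == len(toy_complex.receptor)
        assert np.allclose(back.coords, toy_complex.receptor.coords, atol=1e-3)
        assert list(back.resnum) == list(toy_complex.receptor.resnum)

    def test_multi_model_round_trip(self, small_ensemble, tmp_path):
        path = tmp_path / "ensemble.pdb"
        write_pdb(small_ensemble.conformers[:5], path)
        models = read_models(path)
        assert len(models) == 5
        for a, b in zip(models, small_ensemble.conformers):
            assert np.allclose(a.coords, b.coords, atol=1e-3)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        s = parse_structure(text, fmt="pdb")
        assert len(s) == 1
        assert s.coords[0][0] == pytest.approx(5.0)

    def test_duplicate_atom_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Structure.from_atoms([
                ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                ("A", 1, "ALA", "CA", "C", (1, 0, 0)),
            ])


class TestSasa:
    def test_single_atom_analytic_sphere(self):
        res = shrake_rupley_sasa(single_atom(), probe_radius=1.4, n_points=960)
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert res.total() == pytest.approx(expected, rel=0.01)

    def test_additivity_at_large_separation(self):
        s = Structure.from_atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (100, 0, 0)),
        ])
        res = shrake_rupley_sasa(s)
        single = shrake_rupley_sasa(single_atom()).total()
        assert res.total() == pytest.approx(2 * single, rel=1e-6)

    def test_enclosed_atom_has_zero_sasa(self):
        # cage of 60 atoms at 2.2 A fully occludes the centre
        atoms = [("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))]
        for i, p in enumerate(sphere_points(60), start=2):
            atoms.append(("A", i, "ALA", "CB", "C", tuple(2.2 * p)))
        res = shrake_rupley_sasa(Structure.from_atoms(atoms))
        assert res.per_atom[0] == 0.0

    def test_monte_carlo_oracle_agreement(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 8, size=(20, 3))
        atoms = [("A", i + 1, "ALA", "CA", "C", tuple(c))
                 for i, c in enumerate(coords)]
        s = Structure.from_atoms(atoms)
        result = shrake_rupley_sasa(s, probe_radius=1.4, n_points=960)
        # independent Monte-Carlo surface oracle: random points on each
        # expanded sphere, accessible if outside every other expanded sphere
        radii = np.full(20, 1.7 + 1.4)
        n_mc = 50_000
        total = 0.0
        for i in range(20):
            pts = rng.normal(size=(n_mc, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            surf = coords[i] + radii[i] * pts
            ok = np.ones(n_mc, dtype=bool)
            for j in range(20):
                if j == i:
                    continue
                ok &= np.sum((surf - coords[j]) ** 2, axis=1) > radii[j] ** 2
            total += 4 * np.pi * radii[i] ** 2 * ok.mean()
        assert result.total() == pytest.approx(total, rel=0.02)

    def test_rotation_translation_invariance(self, toy_complex):
        s = toy_complex.ligand
        base = shrake_rupley_sasa(s, n_points=240)
        rot = Rotation.from_euler("xyz", [20, -35, 70], degrees=True).as_matrix()
        moved = s.transformed(rot, np.array([11.0, -3.0, 8.0]))
        res = shrake_rupley_sasa(moved, n_points=240)
        assert np.allclose(res.per_atom, base.per_atom, rtol=0, atol=1e-9)

    def test_relative_sasa_range_and_residue_sums(self, toy_complex):
        res = shrake_rupley_sasa(toy_complex.ligand, n_points=240)
        resnums = sorted(k[1] for k in res.relative)
        for key, rel in res.relative.items():
            if key[1] in (resnums[0], resnums[-1]):
                continue  # chain termini legitimately exceed the GXG maximum
            assert 0.0 <= rel <= 1.2
        # residue SASA equals the sum of its atoms
        i = 0
        key = (str(toy_complex.ligand.chain[i]), int(toy_complex.ligand.resnum[i]))
        mask = toy_complex.ligand.residue_mask([key])
        assert res.per_residue[key] == pytest.approx(res.per_atom[mask].sum())

    def test_unknown_element_warns_and_uses_default(self):
        s = Structure.from_atoms([("A", 1, "ALA", "CA", "QQ", (0, 0, 0))])
        with pytest.warns(UserWarning, match="unknown element"):
            res = shrake_rupley_sasa(s, n_points=240)
        assert res.total() == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)


class TestSuperposition:
    def test_identity_on_same_coordinates(self):
        coords = np.random.default_rng(1).normal(size=(10, 3))
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(12, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        trans = np.array([4.0, -2.0, 9.0])
        moved = coords @ rot.T + trans
        sup = kabsch_superpose(coords, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, rot, atol=1e-9)
        assert np.allclose(sup.translation, trans, atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_minimality_against_random_rotation_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.4, size=(8, 3))
        best = kabsch_superpose(a, b).rmsd
        bc = b - b.mean(axis=0)
        ac = a - a.mean(axis=0)
        for _ in range(1000):
            rot = Rotation.random(random_state=rng).as_matrix()
            assert best <= coords_rmsd(ac @ rot.T, bc) + 1e-9

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="3"):
            kabsch_superpose(line[:2], line[:2])


class TestCaRmsd:
    def residues(self, s):
        return [(c, r) for c, r, _ in s.residue_ids()]

    def test_self_rmsd_zero(self, toy_complex):
        lig = toy_complex.ligand
        assert ca_rmsd(lig, lig, self.residues(lig)) == 0.0

    def test_pythagorean_translation(self, toy_complex):
        lig = toy_complex.ligand
        moved = lig.transformed(np.eye(3), np.array([3.0, 4.0, 0.0]))
        assert ca_rmsd(lig, moved, self.residues(lig)) == pytest.approx(5.0)

    def test_superpose_on_removes_global_shift(self, toy_complex):
        lig = toy_complex.ligand
        moved = lig.transformed(np.eye(3), np.array([3.0, 4.0, 0.0]))
        res = self.residues(lig)
        assert ca_rmsd(lig, moved, res, superpose_on=res) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fixture(self):
        za = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)]
        zb = [(0, 0, 1), (1, 0, 0), (2, 0, 2), (3, 0, 0), (4, 0, 0)]
        a = Structure.from_atoms([("A", i + 1, "GLY", "CA", "C", p)
                                  for i, p in enumerate(za)])
        b = Structure.from_atoms([("A", i + 1, "GLY", "CA", "C", p)
                                  for i, p in enumerate(zb)])
        expected = np.sqrt((1 + 0 + 4 + 0 + 0) / 5)
        res = [("A", i) for i in range(1, 6)]
        assert ca_rmsd(a, b, res) == pytest.approx(expected)

    def test_pseudometric_properties(self, small_ensemble):
        e = small_ensemble
        res = e.loop.residues
        a, b, c = e.conformers[0], e.conformers[1], e.conformers[2]
        dab = ca_rmsd(a, b, res)
        dba = ca_rmsd(b, a, res)
        assert dab == pytest.approx(dba)
        dac = ca_rmsd(a, c, res)
        dbc = ca_rmsd(b, c, res)
        assert dac <= dab + dbc + 1e-9

    def test_missing_ca_named_in_error(self):
        s = Structure.from_atoms([("A", 1, "GLY", "N", "N", (0, 0, 0))])
        with pytest.raises(KeyError, match="A:1"):
            s.ca_coords([("A", 1)])
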