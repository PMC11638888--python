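"""Interaction detectors and per-residue fingerprints on constructed geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pendock import peptides, synth
from pendock.fingerprint import (
    detect_cation_pi,
    detect_hbonds,
    detect_hydrophobic,
    fingerprint_residue,
)
from pendock.structure import Structure

SPLIT = (["A"], ["B"])


def residue_at(chain, resnum, resname, chis=None, rotation=None, translation=None):
    """An isolated ideal residue rigidly placed in the complex frame."""
    backbone = peptides.build_backbone(1, [-120.0], [130.0])[0]
    atoms = peptides.build_side_chain(resname, backbone, chis)
    rot = np.eye(3) if rotation is None else rotation
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    return [(chain, resnum, resname, name, peptides.element_of(name),
             tuple(rot @ pos + trans))
            for name, pos in atoms.items()]


def place_key_atom(atoms_list, key_atom, target):
    """Translate a residue so a named atom lands exactly on ``target``."""
    current = next(np.array(a[5]) for a in atoms_list if a[3] == key_atom)
    shift = np.asarray(target, float) - current
    return [(c, r, rn, n, e, tuple(np.array(xyz) + shift))
            for (c, r, rn, n, e, xyz) in atoms_list]


class TestHbonds:
    def build(self, distance):
        # bare functional atoms: Ser OG (donor) opposite Asp OD1 (acceptor)
        return Structure.from_atoms([
            ("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("B", 2, "ASP", "OD1", "O", (distance, 0.0, 0.0)),
        ])

    def test_ser_asp_pair_at_2_8(self):
        (hbond,) = detect_hbonds(self.build(2.8), SPLIT)
        assert {hbond.atoms_a, hbond.atoms_b} == {"OG", "OD1"}
        assert hbond.distance == pytest.approx(2.8, abs=1e-6)

    def test_beyond_cutoff_none(self):
        assert detect_hbonds(self.build(5.0), SPLIT) == []

    def test_carbon_pair_never_a_donor_or_acceptor(self):
        s = Structure.from_atoms([
            ("A", 1, "ALA", "CB", "C", (0, 0, 0)),
            ("B", 2, "ALA", "CB", "C", (2.8, 0, 0)),
        ])
        assert detect_hbonds(s, SPLIT) == []


class TestHydrophobic:
    def test_leu_leu_contact(self):
        a = residue_at("A", 1, "LEU")
        b = residue_at("B", 2, "LEU", translation=(25, 0, 0))
        cd1 = next(np.array(x[5]) for x in a if x[3] == "CD1")
        b = place_key_atom(b, "CD2", cd1 + np.array([3.9, 0, 0]))
        found = detect_hydrophobic(Structure.from_atoms(a + b), SPLIT)
        assert len(found) == 1
        assert found[0].distance <= 3.9 + 1e-6

    def test_beyond_cutoff_none(self):
        s = Structure.from_atoms([
            ("A", 1, "LEU", "CD1", "C", (0.0, 0, 0)),
            ("B", 2, "LEU", "CD1", "C", (6.0, 0, 0)),
        ])
        assert detect_hydrophobic(s, SPLIT, d_cutoff=4.5) == []

    def test_arg_aliphatic_only(self):
        # CD of Arg counts as apolar, the guanidino NH1 never does
        arg_cd = [("A", 1, "ARG", "CD", "C", (0.0, 0, 0))]
        arg_nh = [("A", 2, "ARG", "NH1", "N", (0.0, 10, 0))]
        probe = [("B", 3, "LEU", "CD1", "C", (4.0, 0, 0)),
                 ("B", 4, "LEU", "CD1", "C", (4.0, 10, 0))]
        found = detect_hydrophobic(Structure.from_atoms(arg_cd + arg_nh + probe),
                                   SPLIT)
        partners = {i.residue_a[1] for i in found}
        assert partners == {1}

    def test_one_interaction_per_residue_pair(self):
        a = residue_at("A", 1, "PHE")
        b = residue_at("B", 2, "PHE", translation=(6.0, 0, 0))
        found = detect_hydrophobic(Structure.from_atoms(a + b), SPLIT)
        assert len(found) <= 1


class TestCationPi:
    def stacked(self, separation, cation="ARG"):
        tyr = residue_at("B", 10, "TYR")
        ring_atoms = [np.array(a[5]) for a in tyr
                      if a[3] in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        centroid = np.mean(ring_atoms, axis=0)
        centred = np.vstack(ring_atoms) - centroid
        normal = np.linalg.svd(centred)[2][2]
        if cation == "ARG":
            res = residue_at("A", 20, "ARG",
                             chis={"chi1": 180, "chi2": 180, "chi3": 180, "chi4": 180})
            group = ("CZ", "NH1", "NH2", "NE")
        else:
            res = residue_at("A", 20, "LYS",
                             chis={"chi1": 180, "chi2": 180, "chi3": 180, "chi4": 180})
            group = ("NZ",)
        pts = [np.array(a[5]) for a in res if a[3] in group]
        gc = np.mean(pts, axis=0)
        shift = centroid + separation * normal - gc
        res = [(c, r, rn, n, e, tuple(np.array(x) + shift))
               for (c, r, rn, n, e, x) in res]
        return Structure.from_atoms(res + tyr)

    def test_arg_over_tyr_ring(self):
        found = detect_cation_pi(self.stacked(4.5), SPLIT)
        assert len(found) == 1
        assert found[0].distance == pytest.approx(4.5, abs=0.05)

    def test_too_far(self):
        assert detect_cation_pi(self.stacked(8.0), SPLIT) == []

    def test_lys_nz_over_phe(self):
        found = detect_cation_pi(self.stacked(4.0, cation="LYS"), SPLIT)
        assert len(found) == 1

    def test_his_cationic_only_when_flagged(self):
        his = residue_at("A", 1, "HIS")
        tyr = residue_at("B", 2, "TYR", translation=(25, 0, 0))
        ring = [np.array(a[5]) for a in tyr
                if a[3] in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        centroid = np.mean(ring, axis=0)
        his_ring = [np.array(a[5]) for a in his
                    if a[3] in ("CG", "ND1", "CD2", "CE1", "NE2")]
        shift = centroid + np.array([0, 0, 4.5]) - np.mean(his_ring, axis=0)
        his = [(c, r, rn, n, e, tuple(np.array(x) + shift))
               for (c, r, rn, n, e, x) in his]
        s = Structure.from_atoms(his + tyr)
        assert detect_cation_pi(s, SPLIT, protonated_his=False) == []
        assert len(detect_cation_pi(s, SPLIT, protonated_his=True)) >= 1


class TestFingerprint:
    def test_empty_for_distant_residues(self):
        a = residue_at("A", 1, "TYR")
        b = residue_at("B", 2, "ASP", translation=(50, 0, 0))
        fp = fingerprint_residue(Structure.from_atoms(a + b), SPLIT, ("A", 1))
        assert fp.interactions == []
        assert fp.counts == {"hbond": 0, "hydrophobic": 0, "cation_pi": 0}

    def test_unknown_focal_residue_errors(self, toy_complex):
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        with pytest.raises(KeyError):
            fingerprint_residue(cx, (["R"], ["L"]), ("L", 999))

    def test_engineered_tyrosine_pocket_counts(self):
        """A pocket built to hold exactly 2 hbonds + 3 hydrophobic + 1 cation-pi.

        Serine and aspartate oxygens coordinate the tyrosine hydroxyl, two
        aromatic rings pack coplanar against the ring edges, and an arginine
        supplies both an aliphatic contact at the ring edge and the stacked
        guanidino group over the ring face.  Pocket side chains are laid down
        as bare functional groups at exact coordinates.
        """
        tyr = residue_at("B", 536, "TYR")
        atoms = {a[3]: np.array(a[5]) for a in tyr}
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ring = np.vstack([atoms[n] for n in ring_names])
        centroid = ring.mean(axis=0)
        vt = np.linalg.svd(ring - centroid)[2]
        normal = vt[2]
        a1 = atoms["OH"] - centroid
        a1 -= (a1 @ normal) * normal
        a1 /= np.linalg.norm(a1)                     # in-plane, toward OH
        a2 = np.cross(normal, a1)
        oh = atoms["OH"]
        oh_dir = atoms["OH"] - atoms["CZ"]
        oh_dir /= np.linalg.norm(oh_dir)

        def hexagon(chain, resnum, resname, names, center, u, v, radius=1.39):
            return [(chain, resnum, resname, name, "C",
                     tuple(center + radius * (np.cos(t) * u + np.sin(t) * v)))
                    for name, t in zip(names, np.linspace(0, 2 * np.pi, 7)[:6])]

        pocket = []
        # hbond partners of the hydroxyl (bare oxygens, 2.8 A away)
        d1 = oh_dir + 0.9 * a2
        d1 /= np.linalg.norm(d1)
        pocket.append(("A", 101, "SER", "OG", "O", tuple(oh + 2.8 * d1)))
        d2 = oh_dir - 0.9 * a2
        d2 /= np.linalg.norm(d2)
        od1 = oh + 2.8 * d2
        pocket.append(("A", 102, "ASP", "OD1", "O", tuple(od1)))
        pocket.append(("A", 102, "ASP", "CG", "C", tuple(od1 + 1.25 * d2)))
        pocket.append(("A", 102, "ASP", "OD2", "O",
                       tuple(od1 + 1.25 * d2 + 1.25 * a2)))
        # coplanar aromatic rings on the two in-plane edges
        pocket += hexagon("A", 103, "PHE", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                          centroid + 6.6 * a2, a1, a2)
        pocket += hexagon("A", 104, "TRP", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
                          centroid - 6.6 * a2, a1, a2)
        # arginine: planar guanidino 4.4 A over the ring face; CD at the edge
        g = centroid + 4.4 * normal
        for name, u in (("CZ", None), ("NE", a1),
                        ("NH1", -0.5 * a1 + 0.866 * a2),
                        ("NH2", -0.5 * a1 - 0.866 * a2)):
            pos = g if u is None else g + 1.33 * u
            pocket.append(("A", 105, "ARG", name,
                           "N" if name.startswith("N") else "C", tuple(pos)))
        cd = centroid + 3.3 * normal + 2.3 * a1
        pocket.append(("A", 105, "ARG", "CD", "C", tuple(cd)))
        pocket.append(("A", 105, "ARG", "CG", "C", tuple(cd + 1.52 * a1)))

        cx = Structure.from_atoms(pocket + tyr)
        fp = fingerprint_residue(cx, SPLIT, ("B", 536))
        assert fp.counts["hbond"] == 2
        assert fp.counts["hydrophobic"] == 3
        assert fp.counts["cation_pi"] == 1
        assert {p[1] for p in fp.partners("hbond")} == {101, 102}
        assert {p[1] for p in fp.partners("hydrophobic")} == {103, 104, 105}
        assert {p[1] for p in fp.partners("cation_pi")} == {105}

    def test_bound_toy_complex_matches_pocket_blueprint(self, toy_complex):
        """The motif tyrosine's network in the bound toy pose mirrors the mu2
        pocket: hydrophobic F/W/R-aliphatic, hbonds to D and K, cation-pi to R."""
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        fp = fingerprint_residue(cx, (["R"], ["L"]), ("L", 536))
        assert {p[1] for p in fp.partners("hydrophobic")} == {174, 421, 423}
        assert {p[1] for p in fp.partners("hbond")} == {176, 203}
        assert 423 in {p[1] for p in fp.partners("cation_pi")}
        fl = fingerprint_residue(cx, (["R"], ["L"]), ("L", 539))
        assert {p[1] for p in fl.partners("hydrophobic")} == {401, 420, 422}

    def test_partner_order_symmetry(self, toy_complex):
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        fwd = detect_hydrophobic(cx, (["R"], ["L"]))
        rev = detect_hydrophobic(cx, (["L"], ["R"]))
        fwd_pairs = {frozenset(((i.residue_a[:2]), (i.residue_b[:2]))) for i in fwd}
        rev_pairs = {frozenset(((i.residue_a[:2]), (i.residue_b[:2]))) for i in rev}
        assert fwd_pairs == rev_pairs

    def test_cutoff_monotonicity(self, toy_complex):
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        small = detect_hydrophobic(cx, (["R"], ["L"]), d_cutoff=4.0)
        large = detect_hydrophobic(cx, (["R"], ["L"]), d_cutoff=5.0)
        small_pairs = {(i.residue_a[:2], i.residue_b[:2]) for i in small}
        large_pairs = {(i.residue_a[:2], i.residue_b[:2]) for i in large}
        assert small_pairs <= large_pairs

    def test_rigid_transform_invariance(self, toy_complex):
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        rot = Rotation.from_euler("xyz", [15, 85, -40], degrees=True).as_matrix()
        moved = cx.transformed(rot, np.array([3.0, -9.0, 12.0]))
        fp0 = fingerprint_residue(cx, (["R"], ["L"]), ("L", 536))
        fp1 = fingerprint_residue(moved, (["R"], ["L"]), ("L", 536))
        assert fp0.counts == fp1.counts
        d0 = sorted(round(i.distance, 3) for i in fp0.interactions)
        d1 = sorted(round(i.distance, 3) for i in fp1.interactions)
        assert d0 == d1

    def test_distances_within_kind_cutoffs(self, toy_complex):
        cx = Structure.concatenate([toy_complex.receptor, toy_complex.ligand])
        fp = fingerprint_residue(cx, (["R"], ["L"]), ("L", 536))
        cutoffs = {"hbond": 3.5, "hydrophobic": 4.5, "cation_pi": 6.0}
        for i in fp.interactions:
            assert 0 < i.distance <= cutoffs[i.kind]
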