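"""Interaction fingerprints of a two-partner complex.

Classifies inter-partner contacts into hydrogen bonds (donor/acceptor
heteroatoms), hydrophobic contacts (apolar carbon pairs) and cation-pi
interactions (cationic group centroid against an aromatic ring centroid), and
reports per-residue interaction networks with distances — the machinery behind
"residue X coordinates the motif tyrosine via two hydrogen bonds and a
cation-pi interaction" style statements.

Cutoff defaults (hbond 3.5 A heteroatom-heteroatom, hydrophobic 4.5 A
carbon-carbon, cation-pi 6.0 A centroid-centroid) follow common structural
practice and are fully configurable; one interaction is reported per residue
pair per kind, represented by its closest atom pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .structure import ResidueId, Structure

HBOND_CUTOFF = 3.5
HYDROPHOBIC_CUTOFF = 4.5
CATION_PI_CUTOFF = 6.0

#: Side-chain hydrogen-bond donors per residue (heteroatoms bearing an H).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
#: Side-chain hydrogen-bond acceptors per residue.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

#: Apolar carbons per residue: aliphatic/aromatic carbons that mediate
#: hydrophobic packing.  Charged-group carbons (Arg CZ, carboxylate/amide
#: carbons, Lys CE adjacent to NZ kept) are excluded so "the aliphatic chain
#: of an arginine" is distinguishable from its guanidino group.
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "HIS": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "VAL": ("CB", "CG1", "CG2"),
}

#: Aromatic ring atom sets (centroid definitions).
AROMATIC_RINGS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
#: Cationic group atom sets (centroid definitions).
CATION_GROUPS: dict[str, tuple[str, ...]] = {
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "LYS": ("NZ",),
}
HIS_CATION_GROUP = ("CG", "ND1", "CD2", "CE1", "NE2")


@dataclass(frozen=True)
class Interaction:
    kind: str                    # hbond | hydrophobic | cation_pi
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    atoms_a: str
    atoms_b: str
    distance: float

    def involves(self, chain: str, resnum: int) -> bool:
        return (self.residue_a[0] == chain and self.residue_a[1] == resnum) or (
            self.residue_b[0] == chain and self.residue_b[1] == resnum
        )

    def partner_of(self, chain: str, resnum: int) -> tuple[str, int, str]:
        if self.residue_a[0] == chain and self.residue_a[1] == resnum:
            return self.residue_b
        return self.residue_a


@dataclass
class ResidueFingerprint:
    focal: tuple[str, int, str]
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {"hbond": 0, "hydrophobic": 0, "cation_pi": 0}
        for i in self.interactions:
            out[i.kind] += 1
        return out

    def partners(self, kind: str) -> list[tuple[str, int, str]]:
        c, r, _ = self.focal
        return [i.partner_of(c, r) for i in self.interactions if i.kind == kind]


PartnerSplit = tuple[Iterable[str], Iterable[str]]


def _split_masks(s: Structure, split: PartnerSplit) -> tuple[np.ndarray, np.ndarray]:
    a_chains = {str(c) for c in split[0]}
    b_chains = {str(c) for c in split[1]}
    a = np.array([str(c) in a_chains for c in s.chain])
    b = np.array([str(c) in b_chains for c in s.chain])
    return a, b


def _residue_atoms(s: Structure, idx: np.ndarray):
    """Group atom indices by residue, preserving order."""
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in idx:
        key = (str(s.chain[i]), int(s.resnum[i]), str(s.resname[i]))
        groups.setdefault(key, []).append(int(i))
    return groups


def detect_hbonds(complex_structure: Structure, split: PartnerSplit,
                  d_cutoff: float = HBOND_CUTOFF) -> list[Interaction]:
    """Cross-partner donor/acceptor heteroatom pairs within ``d_cutoff``.

    Without explicit hydrogens (the usual case for models built here) the
    criterion is distance-only between donor and acceptor heteroatoms; one
    hydrogen bond is reported per residue pair, at the closest such pair.
    """
    a_mask, b_mask = _split_masks(complex_structure, split)
    s = complex_structure

    def polar_atoms(mask, role):
        table = SIDECHAIN_DONORS if role == "donor" else SIDECHAIN_ACCEPTORS
        backbone = BACKBONE_DONOR if role == "donor" else BACKBONE_ACCEPTOR
        out = []
        for i in np.flatnonzero(mask):
            resname, atname = str(s.resname[i]), str(s.atname[i])
            if atname == backbone or atname in table.get(resname, ()):
                out.append(i)
        return out

    best: dict[tuple, tuple[float, int, int]] = {}
    for donors, acceptors in ((polar_atoms(a_mask, "donor"), polar_atoms(b_mask, "acceptor")),
                              (polar_atoms(b_mask, "donor"), polar_atoms(a_mask, "acceptor"))):
        for i in donors:
            for j in acceptors:
                d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
                if d > d_cutoff or d <= 0:
                    continue
                ra = (str(s.chain[i]), int(s.resnum[i]), str(s.resname[i]))
                rb = (str(s.chain[j]), int(s.resnum[j]), str(s.resname[j]))
                key = tuple(sorted((ra, rb)))
                if key not in best or d < best[key][0]:
                    best[key] = (d, i, j)
    out = []
    for (ra, rb), (d, i, j) in sorted(best.items()):
        out.append(Interaction(
            "hbond",
            (str(s.chain[i]), int(s.resnum[i]), str(s.resname[i])),
            (str(s.chain[j]), int(s.resnum[j]), str(s.resname[j])),
            str(s.atname[i]), str(s.atname[j]), round(d, 4)))
    return out


def detect_hydrophobic(complex_structure: Structure, split: PartnerSplit,
                       d_cutoff: float = HYDROPHOBIC_CUTOFF) -> list[Interaction]:
    """Residue pairs with apolar-carbon contact within ``d_cutoff`` (closest pair)."""
    a_mask, b_mask = _split_masks(complex_structure, split)
    s = complex_structure

    def apolar(mask):
        out = []
        for i in np.flatnonzero(mask):
            if str(s.atname[i]) in APOLAR_CARBONS.get(str(s.resname[i]), ()):
                out.append(i)
        return out

    a_atoms, b_atoms = apolar(a_mask), apolar(b_mask)
    best: dict[tuple, tuple[float, int, int]] = {}
    for i in a_atoms:
        for j in b_atoms:
            d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
            if d > d_cutoff or d <= 0:
                continue
            key = ((str(s.chain[i]), int(s.resnum[i])), (str(s.chain[j]), int(s.resnum[j])))
            if key not in best or d < best[key][0]:
                best[key] = (d, i, j)
    out = []
    for key, (d, i, j) in sorted(best.items()):
        out.append(Interaction(
            "hydrophobic",
            (str(s.chain[i]), int(s.resnum[i]), str(s.resname[i])),
            (str(s.chain[j]), int(s.resnum[j]), str(s.resname[j])),
            str(s.atname[i]), str(s.atname[j]), round(d, 4)))
    return out


def detect_cation_pi(complex_structure: Structure, split: PartnerSplit,
                     d_cutoff: float = CATION_PI_CUTOFF,
                     protonated_his: bool = False) -> list[Interaction]:
    """Cationic-group centroid vs aromatic-ring centroid pairs within ``d_cutoff``."""
    a_mask, b_mask = _split_masks(complex_structure, split)
    s = complex_structure

    def groups(mask, table):
        found = []
        for key, idx in _residue_atoms(s, np.flatnonzero(mask)).items():
            resname = key[2]
            names = table.get(resname)
            if resname == "HIS" and table is CATION_GROUPS:
                names = HIS_CATION_GROUP if protonated_his else None
            if not names:
                continue
            atoms = [i for i in idx if str(s.atname[i]) in names]
            if len(atoms) == len(names):
                found.append((key, s.coords[atoms].mean(axis=0), "/".join(names)))
        return found

    out = []
    for cat_side, ring_side in ((a_mask, b_mask), (b_mask, a_mask)):
        for cat_key, cat_xyz, cat_label in groups(cat_side, CATION_GROUPS):
            for ring_key, ring_xyz, ring_label in groups(ring_side, AROMATIC_RINGS):
                d = float(np.linalg.norm(cat_xyz - ring_xyz))
                if 0 < d <= d_cutoff:
                    out.append(Interaction("cation_pi", cat_key, ring_key,
                                           cat_label, ring_label, round(d, 4)))
    out.sort(key=lambda i: (i.residue_a, i.residue_b))
    return out


def fingerprint_residue(
    complex_structure: Structure,
    split: PartnerSplit,
    focal: ResidueId,
    hbond_cutoff: float = HBOND_CUTOFF,
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
    cation_pi_cutoff: float = CATION_PI_CUTOFF,
) -> ResidueFingerprint:
    """Union of the three detectors restricted to one focal residue."""
    chain, resnum = str(focal[0]), int(focal[1])
    resname = None
    for c, r, rn in complex_structure.residue_ids():
        if c == chain and r == resnum:
            resname = rn
            break
    if resname is None:
        raise KeyError(f"focal residue {chain}:{resnum} not in complex")
    interactions = [
        i
        for detector, cutoff in (
            (detect_hbonds, hbond_cutoff),
            (detect_hydrophobic, hydrophobic_cutoff),
            (detect_cation_pi, cation_pi_cutoff),
        )
        for i in detector(complex_structure, split, cutoff)
        if i.involves(chain, resnum)
    ]
    return ResidueFingerprint((chain, resnum, resname), interactions)


def fingerprint_report(fp: ResidueFingerprint) -> dict:
    """JSON-ready fingerprint report (distances to 0.1 A)."""
    return {
        "focal": {"chain": fp.focal[0], "resnum": fp.focal[1], "resname": fp.focal[2]},
        "counts": fp.counts,
        "interactions": [
            {
                "kind": i.kind,
                "partner": {
                    "chain": i.partner_of(fp.focal[0], fp.focal[1])[0],
                    "resnum": i.partner_of(fp.focal[0], fp.focal[1])[1],
                    "resname": i.partner_of(fp.focal[0], fp.focal[1])[2],
                },
                "atoms": [i.atoms_a, i.atoms_b],
                "distance_A": round(i.distance, 1),
            }
            for i in fp.interactions
        ],
    }
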