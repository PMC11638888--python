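"""Ideal-geometry peptide construction and cyclic-coordinate-descent closure.

Atoms are placed by the natural-extension reference frame (NeRF) method from
internal coordinates (bond length, bond angle, torsion).  Backbones use ideal
Engh-Huber-like geometry; side chains are built from a compact topology table
with chi angles drawn from a small rotamer set.  These primitives are shared
by the loop-conformer sampler and the synthetic toy-complex generator.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

BOND_CA_CB = 1.530
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = 122.6  # produces the L-configuration

ELEMENT_OF_ATOM_PREFIX = {"C": "C", "N": "N", "O": "O", "S": "S"}


def element_of(atom_name: str) -> str:
    return ELEMENT_OF_ATOM_PREFIX.get(atom_name.strip()[0], "C")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom D bonded to C, given chain A-B-C and internals."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # A-B-C collinear: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Side-chain topology
#
# Each entry: atom name -> (parent chain A, B, C, bond, angle, torsion spec).
# Torsion spec is either a float (degrees) or ("chiN", offset) taken from the
# residue's chi angles.  Parents may be backbone atoms of the same residue.

Chi = tuple[str, float]
TOPOLOGY: dict[str, list[tuple[str, str, str, str, float, float, float | Chi]]] = {
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 114.0, ("chi1", 0.0)),
        ("CD1", "CA", "CB", "CG", 1.525, 110.5, ("chi2", 0.0)),
        ("CD2", "CA", "CB", "CG", 1.525, 110.5, ("chi2", 122.0)),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.525, 110.5, ("chi1", 0.0)),
        ("CG2", "N", "CA", "CB", 1.525, 110.5, ("chi1", 122.0)),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi1", 0.0)),
        ("CG2", "N", "CA", "CB", 1.530, 110.5, ("chi1", 122.0)),
        ("CD1", "CA", "CB", "CG1", 1.520, 113.8, ("chi2", 0.0)),
    ],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi1", 0.0))],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi1", 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi1", 122.0)),
    ],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi1", 0.0))],
    "MET": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi2", 0.0)),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi3", 0.0)),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi2", 0.0)),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi2", 180.0)),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi2", 0.0)),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi2", 180.0)),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi2", 0.0)),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi3", 0.0)),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi3", 180.0)),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi2", 0.0)),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi3", 0.0)),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi3", 180.0)),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi2", 0.0)),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi3", 0.0)),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi4", 0.0)),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi2", 0.0)),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi3", 0.0)),
        ("CZ", "CG", "CD", "NE", 1.329, 124.5, ("chi4", 0.0)),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi1", 0.0)),
        ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 0.0)),
        ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.391, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.391, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.512, 113.9, ("chi1", 0.0)),
        ("CD1", "CA", "CB", "CG", 1.389, 120.8, ("chi2", 0.0)),
        ("CD2", "CA", "CB", "CG", 1.389, 120.8, ("chi2", 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.389, 121.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.389, 121.2, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.378, 119.6, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.498, 114.1, ("chi1", 0.0)),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi2", 0.0)),
        ("CD2", "CA", "CB", "CG", 1.433, 126.6, ("chi2", 180.0)),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.1, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.3, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.392, 118.6, 180.0),
        ("CH2", "CD2", "CE3", "CZ3", 1.372, 121.1, 0.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.492, 113.8, ("chi1", 0.0)),
        ("ND1", "CA", "CB", "CG", 1.380, 122.7, ("chi2", 0.0)),
        ("CD2", "CA", "CB", "CG", 1.354, 131.0, ("chi2", 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.0, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.0, 180.0),
    ],
    "ALA": [],
    "GLY": [],
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Small rotamer library: per chi index, the staggered states to sample from.
ROTAMER_CHOICES = {1: (-60.0, 180.0, 60.0), 2: (180.0, -60.0, 60.0),
                   3: (180.0, -60.0, 60.0), 4: (180.0, -60.0, 60.0)}
DEFAULT_CHI = {"chi1": -60.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0}


def build_side_chain(resname: str, atoms: dict[str, np.ndarray],
                     chis: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    """Extend a residue's backbone atom dict (N, CA, C) with CB and side chain.

    ``chis`` overrides individual chi angles; anything unspecified uses
    :data:`DEFAULT_CHI`.  Residues without a topology entry get CB only.
    """
    resname = resname.upper()
    if resname == "GLY":
        return atoms
    chis = {**DEFAULT_CHI, **(chis or {})}
    out = dict(atoms)
    out["CB"] = place_atom(out["N"], out["C"], out["CA"],
                           BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
    for entry in TOPOLOGY.get(resname, []):
        name, a, b, c, bond, angle, tors = entry
        if isinstance(tors, tuple):
            tors = chis[tors[0]] + tors[1]
        out[name] = place_atom(out[a], out[b], out[c], bond, angle, tors)
    return out


def sample_chis(resname: str, rng: np.random.Generator) -> dict[str, float]:
    """Draw a chi-angle set for a residue from the staggered rotamer choices."""
    n_chi = 0
    for entry in TOPOLOGY.get(resname.upper(), []):
        if isinstance(entry[6], tuple):
            n_chi = max(n_chi, int(entry[6][0][3]))
    return {f"chi{i}": float(rng.choice(ROTAMER_CHOICES[i])) for i in range(1, n_chi + 1)}


def build_backbone(
    n_residues: int,
    phi: np.ndarray,
    psi: np.ndarray,
    start_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    anchor_psi: float = 140.0,
    omega: float = OMEGA_TRANS,
) -> list[dict[str, np.ndarray]]:
    """Chain of backbone atom dicts {N, CA, C, O} from phi/psi torsions.

    ``start_frame`` gives (N, CA, C) of a preceding anchor residue whose psi
    (``anchor_psi``) orients the first peptide bond; without it the first
    residue is laid out canonically at the origin.  ``phi`` and ``psi`` each
    have one entry per built residue; ``psi[i]`` also places the carbonyl O of
    residue i.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if len(phi) != n_residues or len(psi) != n_residues:
        raise ValueError("phi/psi must have one entry per residue")
    residues: list[dict[str, np.ndarray]] = []
    if start_frame is None:
        n0 = np.array([0.0, 0.0, 0.0])
        ca0 = np.array([BOND_N_CA, 0.0, 0.0])
        ang = np.deg2rad(ANGLE_N_CA_C)
        c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        prev = {"N": n0, "CA": ca0, "C": c0}
        residues.append(prev)
        start = 1
    else:
        prev = {"N": np.asarray(start_frame[0], dtype=float),
                "CA": np.asarray(start_frame[1], dtype=float),
                "C": np.asarray(start_frame[2], dtype=float)}
        start = 0
    for i in range(start, n_residues):
        use_psi = anchor_psi if (start_frame is not None and i == 0) else psi[i - 1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, use_psi)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        res = {"N": n, "CA": ca, "C": c}
        residues.append(res)
        prev = res
    for i, res in enumerate(residues):
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O,
                              psi[i] + 180.0)
    return residues


def _cross_rows(u: np.ndarray, r: np.ndarray) -> np.ndarray:
    """u x r for a fixed 3-vector u against rows of r (avoids np.cross overhead)."""
    out = np.empty_like(r)
    out[:, 0] = u[1] * r[:, 2] - u[2] * r[:, 1]
    out[:, 1] = u[2] * r[:, 0] - u[0] * r[:, 2]
    out[:, 2] = u[0] * r[:, 1] - u[1] * r[:, 0]
    return out


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                      angle: float) -> np.ndarray:
    """Rodrigues rotation of points about an axis through ``origin``."""
    u = axis / np.linalg.norm(axis)
    r = coords - origin
    cos, sin = np.cos(angle), np.sin(angle)
    return (origin + cos * r + sin * _cross_rows(u, r)
            + ((1 - cos) * (r @ u))[:, None] * u)


def ccd_close(
    residues: list[dict[str, np.ndarray]],
    target_atoms: np.ndarray,
    max_iterations: int = 150,
    tolerance: float = 0.10,
) -> float:
    """Cyclic coordinate descent: drive the chain's closing atoms onto targets.

    ``residues`` is a mutable list of backbone atom dicts {N, CA, C, O}; the
    last residue's N, CA and C are compared against ``target_atoms`` (3x3).
    Rotations are applied about each phi (N-CA) and psi (CA-C) axis in turn
    using the closed-form optimal angle (Canutescu & Dunbrack).  The dicts
    are updated in place; the final target RMSD is returned.
    """
    order = ("N", "CA", "C", "O")
    n_res = len(residues)
    coords = np.array([res[name] for res in residues for name in order])
    end = np.array([4 * (n_res - 1), 4 * (n_res - 1) + 1, 4 * (n_res - 1) + 2])
    target = np.asarray(target_atoms, dtype=float)

    def target_rmsd() -> float:
        return float(np.sqrt(np.mean(np.sum((coords[end] - target) ** 2, axis=1))))

    # (pivot index, axis-end index, first downstream index); for phi the
    # residue's own C and O move, for psi only its O
    bonds = []
    for i in range(n_res):
        base = 4 * i
        bonds.append((base, base + 1, np.arange(base + 2, 4 * n_res)))      # phi
        if i < n_res - 1:
            down = np.arange(base + 3, 4 * n_res)                            # psi
            bonds.append((base + 1, base + 2, down))
    for _ in range(max_iterations):
        if target_rmsd() <= tolerance:
            break
        for pivot, axis_end, downstream in bonds:
            origin = coords[pivot]
            axis = coords[axis_end] - origin
            axis /= np.linalg.norm(axis)
            moving = coords[end]
            r = moving - origin
            s = r @ axis
            r_perp = r - s[:, None] * axis
            fvec = target - origin - s[:, None] * axis
            b_dir = _cross_rows(axis, r_perp)
            num = float(np.einsum("ij,ij->", fvec, b_dir))
            den = float(np.einsum("ij,ij->", fvec, r_perp))
            theta = np.arctan2(num, den)
            if abs(theta) < 1e-12:
                continue
            coords[downstream] = rotate_about_axis(coords[downstream], origin,
                                                   axis, theta)
    for i, res in enumerate(residues):
        for k, name in enumerate(order):
            res[name] = coords[4 * i + k]
    return target_rmsd()
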