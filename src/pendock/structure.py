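"""Structure I/O, geometry, solvent accessibility and superposition primitives.

The :class:`Structure` container is a flat, numpy-backed atom table (chain,
author residue number, residue name, atom name, element, coordinates) adequate
for the rigid-body and surface computations in this package.  Parsing of PDB
and mmCIF files is delegated to gemmi; writing uses a native fixed-width PDB
writer so ensembles (MODEL/ENDMDL) round-trip as plain text.

Solvent-accessible surface area uses the Shrake-Rupley sphere-point method
with a deterministic golden-spiral point set (default 960 points, probe
1.4 Angstrom).  Relative per-residue SASA is normalised by theoretical
Gly-X-Gly maxima (Tien et al. 2013), the stated denominator behind any
"accessible above X percent" rule used downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

ResidueId = tuple[str, int]  # (chain id, author residue number)

#: Van der Waals radii (Angstrom) for protein heavy atoms plus hydrogen;
#: a single published set (Bondi 1964 as used in protein SASA work).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

#: Theoretical maximum SASA (Angstrom^2) per residue type in a Gly-X-Gly
#: tripeptide (Tien et al. 2013, "theoretical" column); denominator for
#: relative SASA.
MAX_SASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

WATER_NAMES = {"HOH", "WAT", "DOD"}
STANDARD_RESIDUES = set(MAX_SASA_GXG)


@dataclass
class Structure:
    """Flat atom table with unique (chain, residue number, atom name) keys."""

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atname: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray | None = None
    _index: dict[tuple[str, int, str], int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("chain", "resnum", "resname", "atname", "element"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"field {name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        self.resnum = self.resnum.astype(int)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        self._index = {}
        for i in range(n):
            key = (str(self.chain[i]), int(self.resnum[i]), str(self.atname[i]))
            if key in self._index:
                raise ValueError(f"duplicate atom key {key}")
            self._index[key] = i

    # -- construction -----------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[tuple[str, int, str, str, str, Sequence[float]]]
                   ) -> "Structure":
        """Build from (chain, resnum, resname, atom name, element, xyz) tuples."""
        rows = list(atoms)
        if not rows:
            return cls.empty()
        ch, rn, rna, an, el, xyz = zip(*rows)
        return cls(np.array(ch), np.array(rn), np.array(rna), np.array(an),
                   np.array(el), np.array(xyz, dtype=float))

    @classmethod
    def empty(cls) -> "Structure":
        z = np.empty(0, dtype=object)
        return cls(z.copy(), np.empty(0, dtype=int), z.copy(), z.copy(), z.copy(),
                   np.empty((0, 3)))

    @classmethod
    def concatenate(cls, parts: Sequence["Structure"]) -> "Structure":
        return cls(
            np.concatenate([p.chain for p in parts]),
            np.concatenate([p.resnum for p in parts]),
            np.concatenate([p.resname for p in parts]),
            np.concatenate([p.atname for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.vstack([p.coords for p in parts]),
            np.concatenate([p.occupancy for p in parts]),
        )

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(self.chain[mask], self.resnum[mask], self.resname[mask],
                         self.atname[mask], self.element[mask], self.coords[mask],
                         self.occupancy[mask])

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, resname) triples."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for i in range(len(self)):
            key = (str(self.chain[i]), int(self.resnum[i]))
            if key not in seen:
                seen[key] = str(self.resname[i])
                order.append((key[0], key[1], seen[key]))
        return order

    def residue_mask(self, residues: Iterable[ResidueId]) -> np.ndarray:
        wanted = {(str(c), int(r)) for c, r in residues}
        return np.array([(str(c), int(r)) in wanted
                         for c, r in zip(self.chain, self.resnum)])

    def atom_index(self, chain: str, resnum: int, atname: str) -> int:
        key = (str(chain), int(resnum), str(atname))
        if key not in self._index:
            raise KeyError(f"atom {key} not in structure")
        return self._index[key]

    def atom_coord(self, chain: str, resnum: int, atname: str) -> np.ndarray:
        return self.coords[self.atom_index(chain, resnum, atname)]

    def has_atom(self, chain: str, resnum: int, atname: str) -> bool:
        return (str(chain), int(resnum), str(atname)) in self._index

    def ca_coords(self, residues: Iterable[ResidueId]) -> np.ndarray:
        """C-alpha coordinates in the order of ``residues``; errors name the residue."""
        rows = []
        for c, r in residues:
            try:
                rows.append(self.atom_coord(c, r, "CA"))
            except KeyError:
                raise KeyError(f"residue {c}:{r} has no CA atom") from None
        return np.array(rows).reshape(-1, 3)

    def heavy_mask(self) -> np.ndarray:
        return np.array([str(e).upper() != "H" for e in self.element])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def copy(self) -> "Structure":
        return Structure(self.chain.copy(), self.resnum.copy(), self.resname.copy(),
                         self.atname.copy(), self.element.copy(), self.coords.copy(),
                         self.occupancy.copy())


# ---------------------------------------------------------------------------
# Parsing and writing


class StructureParseError(ValueError):
    pass


def parse_structure(source: str | Path, fmt: str | None = None) -> Structure:
    """Parse a PDB or mmCIF file (path or literal text) into a :class:`Structure`.

    Alternate locations are collapsed to the highest-occupancy conformer; the
    first model of a multi-model file is returned (use :func:`read_models` for
    ensembles).  Hydrogens are retained if present.
    """
    import gemmi

    text, name = _read_source(source)
    if fmt is None:
        fmt = "mmcif" if (name.endswith(".cif") or text.lstrip().startswith("data_")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {name}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{name}: no models")
    return _model_to_structure(st[0])


def read_models(source: str | Path, fmt: str | None = None) -> list[Structure]:
    """Read every model of a multi-model (MODEL/ENDMDL) file."""
    import gemmi

    text, name = _read_source(source)
    if fmt is None:
        fmt = "mmcif" if (name.endswith(".cif") or text.lstrip().startswith("data_")) else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb_string(text)
    else:
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    return [_model_to_structure(model) for model in st]


def _read_source(source: str | Path) -> tuple[str, str]:
    if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists()):
        path = Path(source)
        return path.read_text(), path.name
    return str(source), "<string>"


def _model_to_structure(model) -> Structure:
    by_key: dict[tuple[str, int, str], tuple] = {}
    for chain in model:
        for residue in chain:
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                occ = atom.occ if atom.occ else 1.0
                if key in by_key and occ <= by_key[key][4]:
                    continue  # keep the highest-occupancy altloc
                by_key[key] = (key, residue.name, atom.element.name.upper(),
                               (atom.pos.x, atom.pos.y, atom.pos.z), occ)
    atoms = list(by_key.values())
    ch = np.array([a[0][0] for a in atoms])
    rn = np.array([a[0][1] for a in atoms], dtype=int)
    rna = np.array([a[1] for a in atoms])
    an = np.array([a[0][2] for a in atoms])
    el = np.array([a[2] for a in atoms])
    xyz = np.array([a[3] for a in atoms], dtype=float).reshape(-1, 3)
    occ = np.array([a[4] for a in atoms], dtype=float)
    return Structure(ch, rn, rna, an, el, xyz, occ)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: one-letter elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path | None = None
              ) -> str:
    """Write one structure (or a MODEL/ENDMDL ensemble) in fixed-width PDB format."""
    models = [structures] if isinstance(structures, Structure) else list(structures)
    buf = io.StringIO()
    multi = len(models) > 1
    for imodel, s in enumerate(models, start=1):
        if multi:
            buf.write(f"MODEL     {imodel:4d}\n")
        for i in range(len(s)):
            name = _format_atom_name(str(s.atname[i]), str(s.element[i]))
            x, y, z = s.coords[i]
            buf.write(
                f"ATOM  {i + 1 % 100000:5d} {name}{'':1s}{str(s.resname[i])[:3]:>3s} "
                f"{str(s.chain[i])[:1]:1s}{int(s.resnum[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{float(s.occupancy[i]):6.2f}{0.0:6.2f}"
                f"          {str(s.element[i]).upper():>2s}\n"
            )
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


@dataclass
class SasaResult:
    per_atom: np.ndarray                     # Angstrom^2, aligned with structure atoms
    per_residue: dict[ResidueId, float]      # Angstrom^2
    relative: dict[ResidueId, float]         # fraction of residue-type maximum
    resnames: dict[ResidueId, str]

    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """A right-handed frame fixed to the molecule (principal axes with a
    deterministic sign convention), so surface sampling — and hence SASA —
    is invariant under rigid transforms of the whole structure."""
    centred = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return np.eye(3)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axes = vt.copy()
    for k in range(min(3, len(axes))):
        proj = centred @ axes[k]
        skew = np.sum(proj**3)
        if skew < 0 or (skew == 0 and proj.max() + proj.min() < 0):
            axes[k] = -axes[k]
    if len(axes) < 3:
        return np.eye(3)
    axes[2] = np.cross(axes[0], axes[1])  # enforce right-handedness
    return axes


def shrake_rupley_sasa(
    s: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is expanded by the probe radius and sampled with a fixed
    golden-spiral point set; a point is accessible when outside every
    neighbouring expanded sphere.  Waters (and, unless ``include_het``,
    non-standard residues) are excluded.  Deterministic for a fixed point set.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    mask = np.ones(len(s), dtype=bool)
    for i in range(len(s)):
        rn = str(s.resname[i])
        if rn in WATER_NAMES or (not include_het and rn not in STANDARD_RESIDUES):
            mask[i] = False
    sub = s.subset(mask)
    n = len(sub)
    per_atom_full = np.zeros(len(s))
    if n > 0:
        radii = np.empty(n)
        for i in range(n):
            el = str(sub.element[i]).upper()
            if el not in VDW_RADII:
                warnings.warn(f"unknown element {el!r}; using default vdW radius "
                              f"{default_radius} A")
            radii[i] = VDW_RADII.get(el, default_radius) + probe_radius
        pts = sphere_points(n_points) @ _molecular_frame(sub.coords)
        tree = cKDTree(sub.coords)
        max_r = radii.max()
        areas = np.zeros(n)
        for i in range(n):
            neigh = [j for j in tree.query_ball_point(sub.coords[i], radii[i] + max_r)
                     if j != i]
            surface = sub.coords[i] + radii[i] * pts
            accessible = np.ones(n_points, dtype=bool)
            for j in neigh:
                d2 = np.einsum("ij,ij->i", surface - sub.coords[j], surface - sub.coords[j])
                accessible &= d2 > radii[j] ** 2
                if not accessible.any():
                    break
            areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
        per_atom_full[np.flatnonzero(mask)] = areas
    per_res: dict[ResidueId, float] = {}
    resnames: dict[ResidueId, str] = {}
    for i in np.flatnonzero(mask):
        key = (str(s.chain[i]), int(s.resnum[i]))
        per_res[key] = per_res.get(key, 0.0) + per_atom_full[i]
        resnames[key] = str(s.resname[i])
    relative = {}
    for key, area in per_res.items():
        ref = MAX_SASA_GXG.get(resnames[key])
        relative[key] = area / ref if ref else float("nan")
    return SasaResult(per_atom_full, per_res, relative, resnames)


def sasa_report(result: SasaResult) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    keys = sorted(result.per_residue)
    return pd.DataFrame(
        {
            "chain": [k[0] for k in keys],
            "resnum": [k[1] for k in keys],
            "resname": [result.resnames[k] for k in keys],
            "sasa_A2": [result.per_residue[k] for k in keys],
            "rel_sasa": [result.relative[k] for k in keys],
        }
    )


# ---------------------------------------------------------------------------
# Superposition and RMSD


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform y = R x + t minimising RMSD over a pairing."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares superposition of paired coordinate sets (Kabsch/SVD).

    Returns the proper rotation (det = +1) and translation mapping ``mobile``
    onto ``target`` with minimal RMSD.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if mob.shape != tgt.shape:
        raise ValueError("paired coordinate sets must have equal shapes")
    if len(mob) < 3:
        raise ValueError("need at least 3 paired atoms")
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    m0, t0 = mob - mc, tgt - tc
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    h = m0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    moved = m0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - t0) ** 2, axis=1))))
    return Superposition(rot, trans, rmsd)


def coords_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ca_rmsd(
    a: Structure,
    b: Structure,
    residues: Sequence[ResidueId],
    superpose_on: Sequence[ResidueId] | None = None,
) -> float:
    """C-alpha RMSD over ``residues``, optionally after fitting on another selection.

    With ``superpose_on`` the superposition is computed on that selection and
    the RMSD measured on ``residues`` without re-fitting (the convention for
    loop RMSD after core superposition).
    """
    xa = a.ca_coords(residues)
    xb = b.ca_coords(residues)
    if superpose_on is not None:
        sup = kabsch_superpose(a.ca_coords(superpose_on), b.ca_coords(superpose_on))
        xa = sup.apply(xa)
    return coords_rmsd(xa, xb)
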