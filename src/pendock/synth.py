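"""Seeded synthetic-data generators with machine-readable ground truth.

Every input class the pipeline consumes can be generated here with known
truth: protein sequences with planted sorting motifs, ortholog alignments
with controlled column conservation, a toy receptor/peptide complex with a
known bound pose and extractable restraints, loop-conformer ensembles with
planted cluster structure, and fluorescence images with planted per-cell
intensities over noisy background.  All generators are pure functions of
their parameters and seed.

The toy complex emulates the arrangement of a tyrosine-based sorting motif
bound to the mu2 pocket of the AP-2 adaptor: a YKNL-containing peptide whose
tyrosine is coordinated by an engineered pocket (two hydrogen-bond partners,
two aromatic packing partners and an arginine providing both an aliphatic
contact and a cation-pi interaction) and whose leucine packs against two
valines and a lysine aliphatic chain.  Geometry is coarse (ideal residues,
no refinement) but adequate for SASA, clash, contact and fingerprint typing,
keeping docking runs desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import peptides
from .docking import ActivePassiveSpec, Restraint, extract_ca_restraints
from .loops import ConformerEnsemble, LoopDefinition
from .sequences import (
    DEFAULT_PHI_SET,
    Alignment,
    ProteinSequence,
    scan_yxxphi_regex,
)
from .structure import ResidueId, Structure, kabsch_superpose, sphere_points

NON_TYROSINE_ALPHABET = "ACDEFGHIKLMNPQRSTVW"  # uniform background, no Y


# ---------------------------------------------------------------------------
# Sequences and alignments


def gen_motif_sequences(
    n: int,
    length: int,
    planted: list[tuple[int, str]] | None = None,
    seed: int = 0,
    phi_set=DEFAULT_PHI_SET,
) -> tuple[list[ProteinSequence], dict[str, list[int]]]:
    """Random sequences with motif windows planted at fixed 1-based positions.

    Background residues are uniform over the non-tyrosine alphabet, so every
    tyrosine comes from a planted window.  The returned truth table maps each
    sequence id to all YXXPhi tyrosine positions (planted and incidental),
    enumerated by the regular-expression oracle.
    """
    planted = planted or []
    for pos, window in planted:
        if pos < 1 or pos + len(window) - 1 > length:
            raise ValueError(f"planted window at {pos} does not fit in length {length}")
    spans = sorted((pos, pos + len(window) - 1) for pos, window in planted)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("overlapping planted windows")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(NON_TYROSINE_ALPHABET))
    seqs: list[ProteinSequence] = []
    truth: dict[str, list[int]] = {}
    for i in range(n):
        residues = rng.choice(alphabet, size=length)
        for pos, window in planted:
            residues[pos - 1 : pos - 1 + len(window)] = list(window)
        seq = ProteinSequence(f"synthetic_{i:03d}", "".join(residues))
        seqs.append(seq)
        truth[seq.id] = scan_yxxphi_regex(seq, phi_set)
    return seqs, truth


def gen_ortholog_family(
    reference: ProteinSequence,
    n_rows: int = 10,
    substitution_prob: float = 0.1,
    column_overrides: dict[int, str] | None = None,
    seed: int = 0,
) -> Alignment:
    """Gapless ortholog family: the reference with i.i.d. substitutions.

    ``column_overrides`` maps a 1-based column to an explicit string of
    per-row residues (length ``n_rows``), e.g. to force Phi conservation in
    exactly 7 of 10 rows.  The first row is the unmutated reference.
    """
    if not 0.0 <= substitution_prob <= 1.0:
        raise ValueError("substitution probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ref = list(reference.residues)
    rows: list[tuple[str, str]] = [(reference.id, reference.residues)]
    for i in range(1, n_rows):
        row = list(ref)
        mutate = rng.random(len(row)) < substitution_prob
        subs = rng.choice(alphabet, size=len(row))
        for j in np.flatnonzero(mutate):
            row[j] = str(subs[j])
        rows.append((f"ortholog_{i:02d}", "".join(row)))
    if column_overrides:
        for col, residues in column_overrides.items():
            if len(residues) != n_rows:
                raise ValueError(f"override for column {col} must list {n_rows} residues")
            rows = [
                (rid, gapped[: col - 1] + residues[k] + gapped[col:])
                for k, (rid, gapped) in enumerate(rows)
            ]
    offsets = {rid: reference.numbering_offset for rid, _ in rows}
    return Alignment(rows, offsets)


# ---------------------------------------------------------------------------
# Toy receptor-peptide complex


@dataclass
class ToyComplex:
    """A pocket/peptide complex with known bound pose and derived restraints."""

    receptor: Structure                       # chain R, pocket + shell
    ligand: Structure                         # chain L, bound coordinates
    truth_transform: tuple[np.ndarray, np.ndarray]  # identity: ligand is bound
    restraints: list[Restraint]
    spec: ActivePassiveSpec
    motif_residues: list[ResidueId]           # (chain, resnum) of Y..Phi window
    pocket_residues: list[ResidueId]
    seed: int = 0


def _residue_structure(chain: str, resnum: int, resname: str,
                       atoms: dict[str, np.ndarray]) -> list[tuple]:
    return [(chain, resnum, resname, name, peptides.element_of(name), tuple(pos))
            for name, pos in atoms.items()]


def _build_peptide(sequence: str, start_resnum: int, chain: str = "L",
                   phi: float = -120.0, psi: float = 130.0,
                   chi_overrides: dict[int, dict[str, float]] | None = None) -> Structure:
    n = len(sequence)
    backbone = peptides.build_backbone(n, [phi] * n, [psi] * n)
    chi_overrides = chi_overrides or {}
    atoms = []
    for i, one in enumerate(sequence):
        resname = peptides.ONE_TO_THREE[one]
        resnum = start_resnum + i
        full = peptides.build_side_chain(resname, backbone[i],
                                         chi_overrides.get(resnum))
        atoms.extend(_residue_structure(chain, resnum, resname, full))
    return Structure.from_atoms(atoms)


def _place_residue(resname: str, anchors_mobile: list[np.ndarray],
                   anchors_target: list[np.ndarray],
                   atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rigidly map a built residue so three anchor points best-fit their targets."""
    sup = kabsch_superpose(np.vstack(anchors_mobile), np.vstack(anchors_target))
    return {name: sup.apply(pos.reshape(1, 3))[0] for name, pos in atoms.items()}


def _isolated_residue(resname: str, chis: dict[str, float] | None = None
                      ) -> dict[str, np.ndarray]:
    backbone = peptides.build_backbone(1, [-120.0], [130.0])[0]
    return peptides.build_side_chain(resname, backbone, chis)


def _ring_frame(atoms: dict[str, np.ndarray], ring_names: tuple[str, ...]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ring = np.vstack([atoms[n] for n in ring_names])
    centroid = ring.mean(axis=0)
    centred = ring - centroid
    _, _, vt = np.linalg.svd(centred)
    normal = vt[2] / np.linalg.norm(vt[2])
    axis1 = vt[0] / np.linalg.norm(vt[0])
    return centroid, normal, axis1


def gen_toy_complex(pocket_depth: float = 8.0, peptide_length: int = 8,
                    seed: int = 0) -> ToyComplex:
    """Construct the toy sorting-motif/pocket complex in its bound pose.

    The peptide (chain L) carries the YKNL motif at residues 536-539; the
    receptor (chain R) carries pocket residues numbered like the mu2
    tyrosine-binding pocket (174, 176, 203, 401, 420, 421, 422, 423) plus an
    alanine shell giving the pocket its concavity.  Restraints are extracted
    live from the bound pose; the ground-truth ligand transform is the
    identity.
    """
    if peptide_length < 4:
        raise ValueError("peptide must be at least 4 residues")
    rng = np.random.default_rng(seed)

    # peptide: flank the YKNL core with alternating A/G to the requested length
    left = (peptide_length - 4) // 2
    right = peptide_length - 4 - left
    seq = ("AG" * 4)[:left][::-1] + "YKNL" + ("AG" * 4)[:right]
    start = 536 - left
    ligand = _build_peptide(
        seq, start, chain="L",
        chi_overrides={536: {"chi1": 180.0, "chi2": 90.0},
                       539: {"chi1": 180.0, "chi2": 60.0}},
    )

    lig_atom = lambda resnum, name: ligand.atom_coord("L", resnum, name)  # noqa: E731
    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    tyr_atoms = {n: lig_atom(536, n) for n in ring_names + ("OH", "CB", "CA")}
    y_centroid, y_normal, y_axis1 = _ring_frame(tyr_atoms, ring_names)
    # orient the normal away from the peptide backbone
    backbone_centroid = ligand.coords.mean(axis=0)
    if (y_centroid - backbone_centroid) @ y_normal < 0:
        y_normal = -y_normal
    y_axis2 = np.cross(y_normal, y_axis1)
    oh = tyr_atoms["OH"]
    oh_dir = oh - lig_atom(536, "CZ")
    oh_dir /= np.linalg.norm(oh_dir)

    leu_cd1, leu_cd2 = lig_atom(539, "CD1"), lig_atom(539, "CD2")
    leu_ca = lig_atom(539, "CA")
    leu_mid = 0.5 * (leu_cd1 + leu_cd2)
    leu_dir = leu_mid - leu_ca
    leu_dir /= np.linalg.norm(leu_dir)
    leu_side = np.cross(leu_dir, y_normal)
    leu_side /= np.linalg.norm(leu_side)

    pocket: list[tuple] = []

    def add(resnum: int, resname: str, placed: dict[str, np.ndarray]) -> None:
        pocket.extend(_residue_structure("R", resnum, resname, placed))

    # F174: coplanar aromatic neighbour of the tyrosine ring
    phe = _isolated_residue("PHE")
    pc, pn, pa1 = _ring_frame(phe, ring_names)
    target_c = y_centroid + 6.6 * y_axis2
    add(174, "PHE", _place_residue(
        "PHE",
        [pc, pc + pn, phe["CB"]],
        [target_c, target_c + y_normal,
         target_c + np.linalg.norm(phe["CB"] - pc) * y_axis2],
        phe))

    # W421: aromatic neighbour on the opposite in-plane side
    trp = _isolated_residue("TRP")
    trp_ring = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    tc, tn, _ = _ring_frame(trp, trp_ring)
    target_c = y_centroid - 6.6 * y_axis2
    add(421, "TRP", _place_residue(
        "TRP",
        [tc, tc + tn, trp["CB"]],
        [target_c, target_c + y_normal,
         target_c - np.linalg.norm(trp["CB"] - tc) * y_axis2],
        trp))

    # R423: guanidino group stacked over the ring (cation-pi) with the
    # aliphatic CD passing within hydrophobic range of the ring edge
    arg = _isolated_residue("ARG", {"chi1": 180.0, "chi2": 180.0,
                                    "chi3": 180.0, "chi4": 180.0})
    guan = np.vstack([arg[a] for a in ("CZ", "NH1", "NH2", "NE")]).mean(axis=0)
    t_guan = y_centroid + 4.4 * y_normal
    t_cd = y_centroid + 3.6 * y_normal + 2.1 * y_axis1
    t_cb = y_centroid + 3.3 * y_normal + 4.4 * y_axis1
    add(423, "ARG", _place_residue("ARG", [guan, arg["CD"], arg["CB"]],
                                   [t_guan, t_cd, t_cb], arg))

    # D176 and K203: hydrogen-bond partners of the tyrosine hydroxyl
    asp = _isolated_residue("ASP", {"chi1": 180.0, "chi2": 0.0})
    d_dir = oh_dir + 0.8 * y_axis2
    d_dir /= np.linalg.norm(d_dir)
    t_od1 = oh + 2.8 * d_dir
    t_cg = t_od1 + np.linalg.norm(asp["CG"] - asp["OD1"]) * d_dir
    t_cb = t_cg + 1.53 * (d_dir + 0.6 * y_normal) / np.linalg.norm(d_dir + 0.6 * y_normal)
    add(176, "ASP", _place_residue("ASP", [asp["OD1"], asp["CG"], asp["CB"]],
                                   [t_od1, t_cg, t_cb], asp))

    lys = _isolated_residue("LYS", {"chi1": 180.0, "chi2": 180.0,
                                    "chi3": 180.0, "chi4": 180.0})
    k_dir = oh_dir - 0.8 * y_axis2
    k_dir /= np.linalg.norm(k_dir)
    t_nz = oh + 2.9 * k_dir
    t_ce = t_nz + np.linalg.norm(lys["CE"] - lys["NZ"]) * k_dir
    t_cg = t_nz + np.linalg.norm(lys["CG"] - lys["NZ"]) * (
        k_dir + 0.4 * y_normal) / np.linalg.norm(k_dir + 0.4 * y_normal)
    add(203, "LYS", _place_residue("LYS", [lys["NZ"], lys["CE"], lys["CG"]],
                                   [t_nz, t_ce, t_cg], lys))

    # leucine sub-pocket: V401 and V422 flank the two delta carbons, K420's
    # aliphatic chain caps the tip
    val = _isolated_residue("VAL", {"chi1": 180.0})
    v_mid = 0.5 * (val["CG1"] + val["CG2"])
    for resnum, anchor, lateral in ((401, leu_cd1, leu_side),
                                    (422, leu_cd2, -leu_side)):
        direction = leu_dir + 0.9 * lateral
        direction /= np.linalg.norm(direction)
        t_mid = anchor + 3.8 * direction
        t_cb = t_mid + np.linalg.norm(val["CB"] - v_mid) * direction
        t_ca = t_cb + 1.53 * direction
        add(resnum, "VAL", _place_residue("VAL", [v_mid, val["CB"], val["CA"]],
                                          [t_mid, t_cb, t_ca], val))

    lys420 = _isolated_residue("LYS", {"chi1": 180.0, "chi2": 180.0,
                                       "chi3": 180.0, "chi4": 180.0})
    t_cd = leu_mid + 4.2 * leu_dir
    t_ce = t_cd + np.linalg.norm(lys420["CE"] - lys420["CD"]) * (
        leu_dir + 0.5 * leu_side) / np.linalg.norm(leu_dir + 0.5 * leu_side)
    t_cb = t_cd - np.linalg.norm(lys420["CB"] - lys420["CD"]) * leu_side
    add(420, "LYS", _place_residue("LYS", [lys420["CD"], lys420["CE"], lys420["CB"]],
                                   [t_cd, t_ce, t_cb], lys420))

    pocket_structure = Structure.from_atoms(pocket)

    # alanine shell: hemispherical cap behind the pocket, giving concavity
    pocket_centroid = pocket_structure.coords.mean(axis=0)
    away = pocket_centroid - backbone_centroid
    away /= np.linalg.norm(away)
    shell_atoms: list[tuple] = []
    existing = np.vstack([ligand.coords, pocket_structure.coords])
    resnum = 301
    for radius, n_points in ((pocket_depth, 120), (pocket_depth + 3.0, 160)):
        for point in sphere_points(n_points):
            if point @ away < -0.05:
                continue
            pos = pocket_centroid + radius * point
            if np.linalg.norm(existing - pos, axis=1).min() < 3.2:
                continue
            shell_atoms.append(("R", resnum, "ALA", "CB", "C", tuple(pos)))
            existing = np.vstack([existing, pos[None, :]])
            resnum += 1
    receptor = Structure.concatenate([pocket_structure,
                                      Structure.from_atoms(shell_atoms)])

    pocket_residues: list[ResidueId] = [("R", r) for r in
                                        (174, 176, 203, 401, 420, 421, 422, 423)]
    motif_residues: list[ResidueId] = [("L", r) for r in (536, 537, 538, 539)]
    reference = Structure.concatenate([receptor, ligand])
    pairs = [(("R", r), ("L", 536)) for r in (174, 176, 203, 423)] + [
        (("R", r), ("L", 539)) for r in (401, 420, 422)
    ]
    restraints = extract_ca_restraints(reference, pairs)
    spec = ActivePassiveSpec(
        active_receptor=list(pocket_residues),
        active_ligand=[("L", 536), ("L", 539)],
        passive_ligand=[("L", r) for r in (537, 538)],
    )
    _ = rng  # geometry is deterministic; seed reserved for future stochastic variants
    return ToyComplex(receptor, ligand, (np.eye(3), np.zeros(3)), restraints,
                      spec, motif_residues, pocket_residues, seed)


def validate_toy_complex(toy: ToyComplex, clash_cutoff: float = 2.0,
                         pocket_distance: float = 5.0) -> dict:
    """Check the bound-pose invariants; returns a small report dict."""
    rec_heavy = toy.receptor.coords[toy.receptor.heavy_mask()]
    lig_heavy = toy.ligand.coords[toy.ligand.heavy_mask()]
    d = np.linalg.norm(rec_heavy[:, None, :] - lig_heavy[None, :, :], axis=2)
    min_cross = float(d.min())
    pocket_ok = True
    motif_mask = toy.ligand.residue_mask(toy.motif_residues)
    motif_xyz = toy.ligand.coords[motif_mask]
    for rid in toy.pocket_residues:
        mask = toy.receptor.residue_mask([rid])
        dd = np.linalg.norm(
            toy.receptor.coords[mask][:, None, :] - motif_xyz[None, :, :], axis=2
        )
        if dd.min() > pocket_distance:
            pocket_ok = False
    return {
        "min_cross_distance": min_cross,
        "no_clash": min_cross >= clash_cutoff,
        "pocket_within_reach": pocket_ok,
    }


# ---------------------------------------------------------------------------
# Loop scaffold and planted conformer ensembles


LOOP_SEQUENCE = "AGAYKNLAG"  # residues 533-541; YKNL at 536-539
CORE_RESIDUES = [("A", r) for r in range(521, 532)]  # helix CA set for superposition


def gen_loop_scaffold(seed: int = 0) -> Structure:
    """Helix-loop-helix scaffold on chain A: the motif loop 533-541 between
    two alanine helices (520-532, 542-554) standing in for the rigid core."""
    helix = (-63.0, -43.0)
    loop = (-75.0, -25.0)  # near-helical: keeps the anchors ~15 A apart so
    # resampled loops of the same length can bridge them
    n = 35  # residues 520..554
    phi = np.array([helix[0]] * 13 + [loop[0]] * 9 + [helix[0]] * 13)
    psi = np.array([helix[1]] * 13 + [loop[1]] * 9 + [helix[1]] * 13)
    backbone = peptides.build_backbone(n, phi, psi)
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n):
        resnum = 520 + i
        if 533 <= resnum <= 541:
            resname = peptides.ONE_TO_THREE[LOOP_SEQUENCE[resnum - 533]]
        else:
            resname = "ALA"
        full = peptides.build_side_chain(resname, backbone[i],
                                         peptides.sample_chis(resname, rng))
        atoms.extend(_residue_structure("A", resnum, resname, full))
    return Structure.from_atoms(atoms)


MOTIF_LOOP = LoopDefinition("A", 533, 541, label="motif loop")


def gen_offset_ensemble(
    member_offsets: list[float],
    state_labels: list[int] | None = None,
    seed: int = 0,
) -> ConformerEnsemble:
    """Ensemble whose members are the scaffold loop translated along one axis.

    Translating the whole loop rigidly by ``offset`` makes the pairwise
    loop-CA RMSD between members i and j exactly ``abs(offset_i - offset_j)``,
    which gives full control over the cluster structure seen by the Daura
    algorithm (a calibrated construction; closure onto the anchors is
    deliberately not maintained).
    """
    scaffold = gen_loop_scaffold(seed)
    mask = scaffold.residue_mask(MOTIF_LOOP.residues)
    base = scaffold.subset(mask)
    centroid_all = scaffold.coords.mean(axis=0)
    centroid_loop = base.coords.mean(axis=0)
    u = centroid_loop - centroid_all
    u /= np.linalg.norm(u)
    conformers = [base.transformed(np.eye(3), offset * u) for offset in member_offsets]
    return ConformerEnsemble(scaffold, MOTIF_LOOP, conformers, seed=seed,
                             state_labels=list(state_labels) if state_labels else None)


def two_state_ensemble(sizes: tuple[int, int] = (70, 30), separation: float = 10.0,
                       spread: float = 0.5, seed: int = 0) -> ConformerEnsemble:
    """Two planted conformational states with controlled within-state spread."""
    offsets: list[float] = []
    labels: list[int] = []
    for state, size in enumerate(sizes):
        base = state * separation
        offsets.extend(np.linspace(base, base + spread, size))
        labels.extend([state] * size)
    return gen_offset_ensemble(offsets, labels, seed)


def calibrated_cutoff_ensemble(seed: int = 0) -> ConformerEnsemble:
    """Ensemble whose top-cluster occupancy first peaks at the 2.5 A cutoff.

    The major state is split into two tight sub-lobes 2.3 A apart, so cutoffs
    of 1.5 and 2 A see two half-sized clusters while 2.5 A merges them; two
    distant minor states cap occupancy at larger cutoffs.  The lowest-cutoff/
    highest-occupancy rule must therefore choose 2.5 A.
    """
    offsets: list[float] = []
    labels: list[int] = []
    for lobe_base in (0.0, 2.3):
        offsets.extend(np.linspace(lobe_base, lobe_base + 0.2, 30))
        labels.extend([0] * 30)
    offsets.extend(np.linspace(60.0, 60.3, 20))
    labels.extend([1] * 20)
    offsets.extend(np.linspace(80.0, 80.3, 20))
    labels.extend([2] * 20)
    return gen_offset_ensemble(offsets, labels, seed)


def accessibility_ensemble(seed: int = 0) -> tuple[ConformerEnsemble, list[ResidueId]]:
    """Two-conformer ensemble: an exposed loop and a cage-buried loop.

    The scaffold gains a shell of single-carbon alanine cage residues around
    the native loop site; conformer 0 is translated clear of the cage
    (solvent-exposed motif), conformer 1 sits inside it (buried motif).
    """
    scaffold = gen_loop_scaffold(seed)
    mask = scaffold.residue_mask(MOTIF_LOOP.residues)
    base = scaffold.subset(mask)
    centroid_all = scaffold.coords.mean(axis=0)
    centroid_loop = base.coords.mean(axis=0)
    u = centroid_loop - centroid_all
    u /= np.linalg.norm(u)
    # exposed conformer: an extended build of the loop, held clear of the
    # scaffold, so every motif side chain faces solvent
    extended = _build_peptide(LOOP_SEQUENCE, 533, chain="A")
    shift = centroid_loop + 16.0 * u - extended.coords.mean(axis=0)
    exposed = extended.transformed(np.eye(3), shift)
    buried = base.copy()

    cage_atoms: list[tuple] = []
    existing = np.vstack([scaffold.coords, exposed.coords])
    resnum = 601
    for i in range(len(base)):
        if str(base.atname[i]) not in ("CA", "CB", "CG", "CZ", "CD1", "NZ", "OH"):
            continue
        for point in sphere_points(30):
            pos = base.coords[i] + 5.2 * point
            if np.linalg.norm(existing - pos, axis=1).min() < 3.1:
                continue
            if np.linalg.norm(buried.coords - pos, axis=1).min() < 3.1:
                continue
            cage_atoms.append(("S", resnum, "ALA", "CB", "C", tuple(pos)))
            existing = np.vstack([existing, pos[None, :]])
            resnum += 1
    scaffold_with_cage = Structure.concatenate(
        [scaffold, Structure.from_atoms(cage_atoms)]
    )
    ensemble = ConformerEnsemble(scaffold_with_cage, MOTIF_LOOP, [exposed, buried],
                                 seed=seed, state_labels=[0, 1])
    motif = [("A", r) for r in (536, 537, 538, 539)]
    return ensemble, motif


# ---------------------------------------------------------------------------
# Fluorescence images


@dataclass
class SyntheticImage:
    image: np.ndarray
    cell_masks: list[np.ndarray]
    background_masks: list[np.ndarray]
    truth_ctcf: list[float]
    background: float
    noise_sd: float
    seed: int = 0


def gen_fluorescence_image(
    width: int,
    height: int,
    cells: list[tuple[tuple[float, float], float, float]],
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_background_rois: int = 3,
    background_roi_radius: float = 8.0,
) -> SyntheticImage:
    """Image = background + planted disks + Gaussian noise, with truth CTCF.

    Each cell is ((cx, cy), radius, amplitude); the planted truth CTCF is the
    sum of the amplitude over the disk pixels.  Cells must not overlap and
    must lie inside the frame.  Background ROIs are placed greedily away from
    every cell.
    """
    for (cx, cy), r, _ in cells:
        if not (r <= cx <= width - r and r <= cy <= height - r):
            raise ValueError(f"cell at ({cx}, {cy}) radius {r} leaves the frame")
    for i, ((x1, y1), r1, _) in enumerate(cells):
        for ((x2, y2), r2, _) in cells[i + 1:]:
            if np.hypot(x1 - x2, y1 - y2) < r1 + r2:
                raise ValueError("overlapping cell disks")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    image = np.full((height, width), float(background))
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    cell_masks = []
    truth = []
    for (cx, cy), r, amplitude in cells:
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        image[mask] += amplitude
        cell_masks.append(mask)
        truth.append(float(amplitude) * int(mask.sum()))
    bg_masks: list[np.ndarray] = []
    candidates = [(x, y) for x in np.linspace(background_roi_radius + 1,
                                              width - background_roi_radius - 1, 8)
                  for y in np.linspace(background_roi_radius + 1,
                                       height - background_roi_radius - 1, 8)]
    for x, y in candidates:
        if len(bg_masks) >= n_background_rois:
            break
        clear = all(np.hypot(x - cx, y - cy) > r + background_roi_radius + 2
                    for (cx, cy), r, _ in cells)
        if not clear:
            continue
        if any(np.hypot(x - px, y - py) < 2 * background_roi_radius
               for px, py in [(m.nonzero()[1].mean(), m.nonzero()[0].mean())
                              for m in bg_masks]):
            continue
        bg_masks.append((xx - x) ** 2 + (yy - y) ** 2 <= background_roi_radius**2)
    if len(bg_masks) < n_background_rois:
        raise ValueError("could not place the requested background ROIs")
    return SyntheticImage(image, cell_masks, bg_masks, truth, background, noise_sd, seed)


def gen_ctcf_dataset(
    amplitude_control: float = 12.0,
    effect_ratio: float = 1.63,
    n_control: int = 70,
    n_treatment: int = 73,
    n_replicates_control: int = 6,
    n_replicates_treatment: int = 7,
    radius_range: tuple[float, float] = (10.0, 16.0),
    cell_cv: float = 0.35,
    background: float = 100.0,
    noise_fraction: float = 0.05,
    image_size: int = 96,
    seed: int = 0,
    group_names: tuple[str, str] = ("DMSO", "dynasore"),
):
    """Two-group single-cell image dataset with a planted mean-amplitude ratio.

    One cell per image; per-cell amplitude is lognormal around the group mean
    (coefficient of variation ``cell_cv``), radii uniform in ``radius_range``,
    pixel noise Gaussian with SD ``noise_fraction * background``.  Returns
    measured :class:`~pendock.quantify.CellMeasurement` records via the
    standard ROI measurement path, plus the per-cell truth CTCFs.
    """
    from .quantify import measure_cell

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cell_cv**2))
    measurements = []
    truths = []
    plan = [
        (group_names[0], amplitude_control, n_control, n_replicates_control),
        (group_names[1], amplitude_control * effect_ratio, n_treatment,
         n_replicates_treatment),
    ]
    for group, amp_mean, n_cells, n_reps in plan:
        for i in range(n_cells):
            replicate = f"{group}_rep{i % n_reps + 1}"
            amp = amp_mean * np.exp(rng.normal(-0.5 * sigma**2, sigma))
            radius = rng.uniform(*radius_range)
            centre = (image_size / 2 + rng.uniform(-4, 4),
                      image_size / 2 + rng.uniform(-4, 4))
            img = gen_fluorescence_image(
                image_size, image_size, [(centre, radius, amp)],
                background=background, noise_sd=noise_fraction * background,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            m = measure_cell(img.image, img.cell_masks[0], img.background_masks,
                             cell_id=f"{group}_{i:03d}", replicate=replicate,
                             group=group)
            measurements.append(m)
            truths.append(img.truth_ctcf[0])
    return measurements, truths
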