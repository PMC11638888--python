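"""Distance-restraint-guided rigid-body docking with a staged model funnel.

The docking strategy mirrors how adaptor/cargo complexes are modelled from a
reference structure of a homologous complex: Calpha-Calpha distances between
the cargo motif residues and the adaptor pocket residues are extracted from
the reference and imposed as flat-bottom restraints; candidate poses are
generated from random rigid starts (stage A) or perturbations of a seed pose
(stage B), locally minimised, funnelled (generate -> re-rank -> cluster) and
the final model is the best-energy member of the most populated pose cluster.

The scoring function is a documented surrogate, not a molecular force field:

    total = w_r * restraint + w_c * clash + w_a * contact

with flat-bottom harmonic restraints, a soft quadratic clash penalty below
2.5 Angstrom and a contact reward of -1 per inter-partner heavy-atom pair
within 5 Angstrom.  Default weights are (1.0, 1.0, 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree

from .loops import Cluster, ClusteringResult, daura_cluster_matrix
from .structure import ResidueId, Structure, coords_rmsd

DEFAULT_WEIGHTS = (1.0, 1.0, 0.1)
CLASH_CUTOFF = 2.5      # Angstrom, heavy-atom soft-core onset
CONTACT_CUTOFF = 5.0    # Angstrom, heavy-atom contact reward
POSE_CLUSTER_CUTOFF = 5.0
AIR_TARGET = 5.0        # Angstrom, ambiguous active-residue min-distance target


@dataclass(frozen=True)
class Restraint:
    """Flat-bottom Calpha-Calpha distance restraint between the partners."""

    receptor: ResidueId
    ligand: ResidueId
    target: float
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("restraint target distance must be positive")
        if self.tolerance < 0:
            raise ValueError("restraint tolerance must be >= 0")


@dataclass
class ActivePassiveSpec:
    """Interface definition: active residues must contact the partner interface."""

    active_receptor: list[ResidueId] = field(default_factory=list)
    active_ligand: list[ResidueId] = field(default_factory=list)
    passive_receptor: list[ResidueId] = field(default_factory=list)
    passive_ligand: list[ResidueId] = field(default_factory=list)

    def __post_init__(self) -> None:
        for act, pas in ((self.active_receptor, self.passive_receptor),
                         (self.active_ligand, self.passive_ligand)):
            overlap = set(map(tuple, act)) & set(map(tuple, pas))
            if overlap:
                raise ValueError(f"residues both active and passive: {sorted(overlap)}")


@dataclass(frozen=True)
class DockingProtocol:
    """Funnel parameters of one docking run."""

    stage: str = "A"
    n_generated: int = 200
    n_scored_kept: int = 50
    n_clustered: int = 20
    restraint_tolerance: float = 0.0
    backbone_flexibility: bool = False
    seed: int = 0
    start_radius: float = 15.0
    perturb_rotation_deg: float = 8.0
    perturb_translation: float = 1.0
    cluster_cutoff: float = POSE_CLUSTER_CUTOFF
    minimize_maxfev: int = 150

    def __post_init__(self) -> None:
        if self.stage not in ("A", "B"):
            raise ValueError("stage must be 'A' or 'B'")
        if not (self.n_generated >= self.n_scored_kept >= self.n_clustered >= 1):
            raise ValueError("funnel must satisfy n_generated >= n_scored_kept "
                             ">= n_clustered >= 1")


@dataclass(frozen=True)
class EnergyBreakdown:
    restraint: float
    clash: float
    contact: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    @property
    def total(self) -> float:
        w_r, w_c, w_a = self.weights
        return w_r * self.restraint + w_c * self.clash + w_a * self.contact


@dataclass
class DockedPose:
    """Rigid transform applied to the ligand, with its energy breakdown."""

    rotation: np.ndarray
    translation: np.ndarray
    energy: EnergyBreakdown
    rank: int | None = None
    cluster_id: int | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


IDENTITY_POSE = (np.eye(3), np.zeros(3))


def extract_ca_restraints(
    reference: Structure,
    pairs: list[tuple[ResidueId, ResidueId]],
    tolerance: float = 0.0,
) -> list[Restraint]:
    """One restraint per (receptor residue, ligand residue) pair.

    The target is the Euclidean Calpha-Calpha distance measured in the
    reference complex; the flat-bottom half-width is set by ``tolerance``
    (0 or 0.3 Angstrom in the standard protocols).
    """
    restraints = []
    for rec, lig in pairs:
        try:
            a = reference.atom_coord(rec[0], rec[1], "CA")
        except KeyError:
            raise KeyError(f"receptor residue {rec[0]}:{rec[1]} has no CA in reference") from None
        try:
            b = reference.atom_coord(lig[0], lig[1], "CA")
        except KeyError:
            raise KeyError(f"ligand residue {lig[0]}:{lig[1]} has no CA in reference") from None
        restraints.append(Restraint((rec[0], rec[1]), (lig[0], lig[1]),
                                    float(np.linalg.norm(a - b)), tolerance))
    return restraints


def auto_passive(
    structure: Structure,
    active: list[ResidueId],
    distance: float = 6.5,
    min_relative_sasa: float = 0.2,
    sasa_n_points: int = 240,
) -> list[ResidueId]:
    """Passive residues: near an active residue and solvent exposed."""
    from .structure import shrake_rupley_sasa

    active_set = {(str(c), int(r)) for c, r in active}
    act_mask = structure.residue_mask(active) & structure.heavy_mask()
    if not act_mask.any():
        return []
    tree = cKDTree(structure.coords[act_mask])
    sasa = shrake_rupley_sasa(structure, n_points=sasa_n_points, include_het=True)
    passive = []
    for chain, resnum, _ in structure.residue_ids():
        if (chain, resnum) in active_set:
            continue
        mask = structure.residue_mask([(chain, resnum)]) & structure.heavy_mask()
        if not mask.any():
            continue
        d = tree.query(structure.coords[mask], k=1)[0].min()
        rel = sasa.relative.get((chain, resnum), 0.0)
        if d <= distance and (np.isnan(rel) or rel > min_relative_sasa):
            passive.append((chain, resnum))
    return passive


# ---------------------------------------------------------------------------
# Scoring


class _ScoringContext:
    """Precomputed geometry for fast repeated pose scoring."""

    def __init__(self, receptor: Structure, ligand: Structure,
                 restraints: list[Restraint],
                 spec: ActivePassiveSpec | None = None,
                 weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                 clash_cutoff: float = CLASH_CUTOFF,
                 contact_cutoff: float = CONTACT_CUTOFF):
        self.weights = weights
        self.clash_cutoff = clash_cutoff
        self.contact_cutoff = contact_cutoff
        self.rec_heavy = receptor.coords[receptor.heavy_mask()]
        self.lig_heavy_local = ligand.coords[ligand.heavy_mask()]
        self.rec_ca = np.array(
            [receptor.atom_coord(r.receptor[0], r.receptor[1], "CA") for r in restraints]
        ).reshape(-1, 3)
        self.lig_ca_local = np.array(
            [ligand.atom_coord(r.ligand[0], r.ligand[1], "CA") for r in restraints]
        ).reshape(-1, 3)
        self.targets = np.array([r.target for r in restraints])
        self.tolerances = np.array([r.tolerance for r in restraints])
        self.air_pairs: list[tuple[np.ndarray, bool]] = []
        if spec is not None:
            rec_iface = spec.active_receptor + spec.passive_receptor
            lig_iface = spec.active_ligand + spec.passive_ligand
            rec_iface_xyz = self._heavy(receptor, rec_iface)
            lig_iface_xyz = self._heavy(ligand, lig_iface)
            # each active residue must approach the partner interface
            for rid in spec.active_receptor:
                xyz = self._heavy(receptor, [rid])
                if len(xyz) and len(lig_iface_xyz):
                    self.air_pairs.append((xyz, False))
            for rid in spec.active_ligand:
                xyz = self._heavy(ligand, [rid])
                if len(xyz) and len(rec_iface_xyz):
                    self.air_pairs.append((xyz, True))
            self.rec_iface_xyz = rec_iface_xyz
            self.lig_iface_local = lig_iface_xyz

    @staticmethod
    def _heavy(s: Structure, residues: list[ResidueId]) -> np.ndarray:
        mask = s.residue_mask(residues) & s.heavy_mask()
        return s.coords[mask]

    def restraint_energy(self, rot: np.ndarray, trans: np.ndarray) -> float:
        e = float(np.sum(self.restraint_residuals(rot, trans) ** 2))
        for xyz, is_ligand in self.air_pairs:
            if is_ligand:
                moved = xyz @ rot.T + trans
                d = _min_cross_distance(moved, self.rec_iface_xyz)
            else:
                iface = self.lig_iface_local @ rot.T + trans
                d = _min_cross_distance(xyz, iface)
            e += max(0.0, d - AIR_TARGET) ** 2
        return e

    def restraint_residuals(self, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
        if len(self.targets) == 0:
            return np.zeros(1)
        lig = self.lig_ca_local @ rot.T + trans
        d = np.linalg.norm(lig - self.rec_ca, axis=1)
        viol = np.maximum(0.0, np.abs(d - self.targets) - self.tolerances)
        viol[viol < 1e-9] = 0.0  # numerical dead zone: self-extracted
        # restraints evaluate to exactly zero on their reference complex
        return viol

    def clash_contact(self, rot: np.ndarray, trans: np.ndarray) -> tuple[float, float]:
        lig = self.lig_heavy_local @ rot.T + trans
        d2 = (
            np.sum(lig**2, axis=1)[:, None]
            + np.sum(self.rec_heavy**2, axis=1)[None, :]
            - 2.0 * lig @ self.rec_heavy.T
        )
        np.maximum(d2, 0.0, out=d2)
        near = d2 < self.contact_cutoff**2
        contact = -float(near.sum())
        clash_mask = d2 < self.clash_cutoff**2
        if clash_mask.any():
            d = np.sqrt(d2[clash_mask])
            clash = float(np.sum((self.clash_cutoff - d) ** 2))
        else:
            clash = 0.0
        return clash, contact

    def energy(self, rot: np.ndarray, trans: np.ndarray) -> EnergyBreakdown:
        clash, contact = self.clash_contact(rot, trans)
        return EnergyBreakdown(self.restraint_energy(rot, trans), clash, contact,
                               self.weights)


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d2 = (np.sum(a**2, axis=1)[:, None] + np.sum(b**2, axis=1)[None, :]
          - 2.0 * a @ b.T)
    return float(np.sqrt(max(d2.min(), 0.0)))


def score_pose(
    receptor: Structure,
    ligand: Structure,
    transform: tuple[np.ndarray, np.ndarray] = IDENTITY_POSE,
    restraints: list[Restraint] | None = None,
    spec: ActivePassiveSpec | None = None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    clash_cutoff: float = CLASH_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> EnergyBreakdown:
    """Surrogate energy of the ligand posed by ``transform`` against the receptor."""
    rot, trans = np.asarray(transform[0], dtype=float), np.asarray(transform[1], dtype=float)
    if not (np.isfinite(rot).all() and np.isfinite(trans).all()):
        raise ValueError("non-finite transform")
    ctx = _ScoringContext(receptor, ligand, restraints or [], spec, weights,
                          clash_cutoff, contact_cutoff)
    return ctx.energy(rot, trans)


# ---------------------------------------------------------------------------
# Pose generation and the funnel


def _pose_params_to_transform(x: np.ndarray, base_rot: np.ndarray,
                              base_trans: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    delta = Rotation.from_rotvec(x[:3]).as_matrix()
    return delta @ base_rot, delta @ base_trans + x[3:]


def _minimize_pose(ctx: _ScoringContext, rot0: np.ndarray, trans0: np.ndarray,
                   maxfev: int) -> tuple[np.ndarray, np.ndarray]:
    # stage 1: restraint-only least squares (smooth, cheap residuals)
    def residuals(x):
        rot, trans = _pose_params_to_transform(x, rot0, trans0)
        return ctx.restraint_residuals(rot, trans)

    if len(ctx.targets):
        sol = least_squares(residuals, np.zeros(6), method="lm", max_nfev=200)
        rot1, trans1 = _pose_params_to_transform(sol.x, rot0, trans0)
    else:
        rot1, trans1 = rot0, trans0

    # stage 1b: distance restraints to a few ligand CAs leave the rotation
    # about the axis through the restrained CAs (nearly) unconstrained; scan
    # that axis explicitly and keep the best-energy angle
    unique_ca = np.unique(np.round(ctx.lig_ca_local, 6), axis=0)
    if len(unique_ca) >= 2:
        sep = np.linalg.norm(unique_ca[:, None, :] - unique_ca[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmax(sep), sep.shape)
        axis_local = unique_ca[j] - unique_ca[i]
        axis_world = rot1 @ (axis_local / np.linalg.norm(axis_local))
        pivot = rot1 @ unique_ca[i] + trans1
        best_e = ctx.energy(rot1, trans1).total
        best = (rot1, trans1)
        for theta in np.deg2rad(np.arange(15.0, 360.0, 15.0)):
            r_axis = Rotation.from_rotvec(theta * axis_world).as_matrix()
            rot_s = r_axis @ rot1
            trans_s = r_axis @ trans1 + pivot - r_axis @ pivot
            e = ctx.energy(rot_s, trans_s).total
            if e < best_e:
                best_e = e
                best = (rot_s, trans_s)
        rot1, trans1 = best

    # stage 2: short derivative-free refinement of the full surrogate energy
    def objective(x):
        rot, trans = _pose_params_to_transform(x, rot1, trans1)
        return ctx.energy(rot, trans).total

    res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                   options=dict(maxfev=maxfev, xatol=1e-3, fatol=1e-4))
    best = res.x if res.fun <= objective(np.zeros(6)) else np.zeros(6)
    return _pose_params_to_transform(best, rot1, trans1)


def dock(
    receptor: Structure,
    ligand: Structure,
    restraints: list[Restraint],
    spec: ActivePassiveSpec | None = None,
    protocol: DockingProtocol = DockingProtocol(),
    seed_pose: tuple[np.ndarray, np.ndarray] | None = None,
    receptor_variants: list[Structure] | None = None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> tuple[list[DockedPose], ClusteringResult]:
    """Staged rigid-body docking; returns (ranked poses, head-pose clustering).

    Stage A starts each candidate from a uniformly random ligand orientation
    placed within ``protocol.start_radius`` of the receptor's active-residue
    centroid; stage B perturbs ``seed_pose``.  Every start is locally
    minimised (restraint least-squares followed by a short full-energy
    refinement), the ``n_scored_kept`` best are re-ranked, and the
    ``n_clustered`` best are clustered on ligand-CA RMSD; cluster ids and
    final ranks are attached.  With both stage-B perturbation amplitudes at
    zero the seed pose is scored as-is (a fixed point of the protocol).

    With ``protocol.backbone_flexibility`` and ``receptor_variants``, the
    generation budget is split across the variants and the pose pools merged,
    approximating backbone flexibility of the remodelled loop.
    """
    if protocol.restraint_tolerance and restraints:
        restraints = [replace(r, tolerance=protocol.restraint_tolerance)
                      for r in restraints]
    variants = [receptor]
    if protocol.backbone_flexibility and receptor_variants:
        variants = list(receptor_variants)
    rng = np.random.default_rng(protocol.seed)
    if protocol.stage == "B" and seed_pose is None:
        raise ValueError("stage B requires a seed pose")

    poses: list[DockedPose] = []
    per_variant = int(np.ceil(protocol.n_generated / len(variants)))
    frozen = (protocol.stage == "B" and protocol.perturb_rotation_deg == 0.0
              and protocol.perturb_translation == 0.0)
    for variant in variants:
        ctx = _ScoringContext(variant, ligand, restraints, spec, weights)
        centroid = _start_centroid(variant, spec, restraints)
        lig_center = ligand.coords[ligand.heavy_mask()].mean(axis=0)
        n_here = min(per_variant, protocol.n_generated - len(poses))
        for _ in range(n_here):
            if protocol.stage == "A":
                rot0 = Rotation.random(random_state=rng).as_matrix()
                offset = _random_in_sphere(rng, protocol.start_radius)
                trans0 = centroid + offset - rot0 @ lig_center
            else:
                rot_seed, trans_seed = seed_pose
                dr = Rotation.from_rotvec(
                    rng.normal(0.0, np.deg2rad(protocol.perturb_rotation_deg), 3)
                ).as_matrix()
                rot0 = dr @ np.asarray(rot_seed, dtype=float)
                trans0 = (dr @ np.asarray(trans_seed, dtype=float)
                          + rng.normal(0.0, protocol.perturb_translation, 3))
            if frozen:
                rot, trans = np.asarray(seed_pose[0], dtype=float), \
                    np.asarray(seed_pose[1], dtype=float)
            else:
                rot, trans = _minimize_pose(ctx, rot0, trans0, protocol.minimize_maxfev)
            e = ctx.energy(rot, trans)
            if not np.isfinite(e.total):
                continue
            poses.append(DockedPose(rot, trans, e))
    if not poses:
        raise RuntimeError("no pose with finite energy was generated")

    # funnel: keep best-scored, re-rank, cluster the head of the list
    poses.sort(key=lambda p: p.energy.total)
    kept = poses[: protocol.n_scored_kept]
    # re-ranking uses the same surrogate energy (documented divergence from
    # an explicit-solvent rescoring stage)
    kept.sort(key=lambda p: p.energy.total)
    head = kept[: protocol.n_clustered]
    clustered = cluster_poses(head, ligand, cutoff=protocol.cluster_cutoff)
    for rank, pose in enumerate(kept, start=1):
        pose.rank = rank
    return kept, clustered


def _start_centroid(receptor: Structure, spec: ActivePassiveSpec | None,
                    restraints: list[Restraint]) -> np.ndarray:
    if spec is not None and spec.active_receptor:
        mask = receptor.residue_mask(spec.active_receptor)
        return receptor.coords[mask].mean(axis=0)
    if restraints:
        cas = np.array([receptor.atom_coord(r.receptor[0], r.receptor[1], "CA")
                        for r in restraints])
        return cas.mean(axis=0)
    return receptor.coords.mean(axis=0)


def _random_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.uniform() ** (1.0 / 3.0)


def cluster_poses(poses: list[DockedPose], ligand: Structure,
                  cutoff: float = POSE_CLUSTER_CUTOFF) -> ClusteringResult:
    """Daura exclusive clustering of poses on ligand-CA RMSD (shared receptor frame)."""
    ca_mask = np.array([a == "CA" for a in ligand.atname])
    local = ligand.coords[ca_mask]
    placed = [local @ p.rotation.T + p.translation for p in poses]
    n = len(poses)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = coords_rmsd(placed[i], placed[j])
    result = daura_cluster_matrix(mat, cutoff)
    for cid, cluster in enumerate(result.clusters):
        for m in cluster.members:
            poses[m].cluster_id = cid
    return result


def select_final_model(
    poses: list[DockedPose],
    clustering: ClusteringResult,
    size_fraction: float = 1.0,
) -> DockedPose:
    """Best-energy pose among the most populated pose clusters.

    Clusters whose size is at least ``size_fraction`` of the maximum qualify
    (default: only maximal-size clusters, ties allowed); the lowest total
    energy among their members wins.
    """
    if not clustering.clusters:
        raise ValueError("no clusters to select from")
    max_size = clustering.clusters[0].size
    candidates = [
        m for c in clustering.clusters if c.size >= size_fraction * max_size
        for m in c.members
    ]
    return min((poses[m] for m in candidates), key=lambda p: p.energy.total)


def ligand_rmsd(pose: DockedPose, reference: tuple[np.ndarray, np.ndarray],
                ligand: Structure) -> float:
    """CA RMSD between the ligand under ``pose`` and under a reference transform."""
    ca_mask = np.array([a == "CA" for a in ligand.atname])
    local = ligand.coords[ca_mask]
    ref_rot, ref_trans = reference
    a = local @ pose.rotation.T + pose.translation
    b = local @ np.asarray(ref_rot).T + np.asarray(ref_trans)
    return coords_rmsd(a, b)


def restraints_table(restraints: list[Restraint]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "rec_chain": [r.receptor[0] for r in restraints],
            "rec_res": [r.receptor[1] for r in restraints],
            "lig_chain": [r.ligand[0] for r in restraints],
            "lig_res": [r.ligand[1] for r in restraints],
            "target_A": [r.target for r in restraints],
            "tol_A": [r.tolerance for r in restraints],
        }
    )
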