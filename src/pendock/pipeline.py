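"""End-to-end orchestration of the structural and quantification analyses.

The structural pipeline mirrors the two-run modelling design used for
cargo/mu2 complexes: remodel the motif-bearing loop (conformer pool ->
Daura clustering over a cutoff ladder -> lowest-cutoff/highest-occupancy
selection -> cluster representatives screened by motif solvent exposure),
then dock the motif peptide into the pocket with restraints extracted from
the reference bound pose (stage A from random starts; its selected model
seeds stage B), and fingerprint the final complex.

The quantification pipeline turns per-cell fluorescence into CTCF values,
SuperPlot group summaries and two-group statistics.

All randomness flows from the seeds in the configuration; rerunning with the
same configuration reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import docking, loops, synth
from .fingerprint import fingerprint_report, fingerprint_residue
from .quantify import compare_groups, measurements_table, summarize_superplot
from .sequences import classify_motifs, scan_yxxphi
from .structure import Structure, write_pdb


@dataclass
class PipelineConfig:
    """Run parameters; defaults are the standard study-scale settings."""

    seed: int = 11
    # loop stage
    ensemble_size: int = 10_000
    cutoff_ladder: tuple[float, ...] = loops.DEFAULT_CUTOFFS
    sasa_threshold: float = 0.60
    sasa_points: int = 960
    # docking stage
    n_generated: int = 2000
    n_scored_kept: int = 500
    n_clustered: int = 200
    restraint_tolerance: float = 0.0
    # quantification stage
    effect_ratio: float = 1.63
    n_control: int = 70
    n_treatment: int = 73
    # motif scanning
    motif_region: tuple[int, int] | None = None
    phi_set: str = "LIMFV"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (self.n_generated >= self.n_scored_kept >= self.n_clustered >= 1):
            raise ValueError("funnel counts must be non-increasing")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def fast_config(seed: int = 11) -> PipelineConfig:
    """Desk-scale profile for tests and demonstrations."""
    return PipelineConfig(seed=seed, ensemble_size=60, n_generated=200,
                          n_scored_kept=50, n_clustered=20, sasa_points=480,
                          n_control=24, n_treatment=24)


def run_structural_pipeline(config: PipelineConfig,
                            out_dir: str | Path | None = None) -> dict:
    """Motif -> loop ensemble -> docking -> fingerprint on the synthetic system.

    Returns a JSON-ready report; when ``out_dir`` is given, the report, the
    final complex (PDB) and stage tables are written there.
    """
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "loop_ensemble"
    try:
        scaffold = synth.gen_loop_scaffold(seed=config.seed)
        ensemble = loops.sample_loop_conformations(
            scaffold, synth.MOTIF_LOOP, n=config.ensemble_size, seed=config.seed
        )
        selection = loops.select_cutoff(ensemble, config.cutoff_ladder,
                                        superpose_on=synth.CORE_RESIDUES)
        clustering = selection.clusterings[selection.cutoff]
        reps = [c.representative for c in clustering.clusters]
        motif = [("A", r) for r in (536, 537, 538, 539)]
        accessible = loops.select_accessible_model(
            ensemble, reps[: min(len(reps), 10)], motif,
            threshold=config.sasa_threshold, n_points=config.sasa_points,
        )
        report["loop_stage"] = {
            "ensemble_size": len(ensemble),
            "chosen_cutoff_A": float(selection.cutoff),
            "occupancy_by_cutoff": {str(k): float(round(v, 4))
                                    for k, v in selection.occupancy_by_cutoff.items()},
            "n_clusters": len(clustering.clusters),
            "selected_conformer": accessible.index,
            "min_motif_relative_sasa": float(round(accessible.min_relative_sasa, 4)),
            "sasa_rule_passed": accessible.passed,
        }

        stage = "docking"
        toy = synth.gen_toy_complex(seed=config.seed)
        protocol_a = docking.DockingProtocol(
            stage="A", n_generated=config.n_generated,
            n_scored_kept=config.n_scored_kept, n_clustered=config.n_clustered,
            restraint_tolerance=config.restraint_tolerance, seed=config.seed,
        )
        poses_a, clusters_a = docking.dock(toy.receptor, toy.ligand, toy.restraints,
                                           toy.spec, protocol_a)
        seed_model = docking.select_final_model(poses_a, clusters_a)
        protocol_b = dataclasses.replace(protocol_a, stage="B", seed=config.seed + 1)
        poses_b, clusters_b = docking.dock(
            toy.receptor, toy.ligand, toy.restraints, toy.spec, protocol_b,
            seed_pose=(seed_model.rotation, seed_model.translation),
        )
        final = docking.select_final_model(poses_b, clusters_b)
        rmsd_truth = docking.ligand_rmsd(final, toy.truth_transform, toy.ligand)
        report["docking_stage"] = {
            "n_restraints": len(toy.restraints),
            "stage_a_best_energy": float(round(seed_model.energy.total, 3)),
            "final_energy": {
                "restraint": float(round(final.energy.restraint, 4)),
                "clash": float(round(final.energy.clash, 4)),
                "contact": float(final.energy.contact),
                "total": float(round(final.energy.total, 3)),
            },
            "final_ligand_rmsd_to_truth_A": float(round(rmsd_truth, 3)),
        }

        stage = "fingerprint"
        placed_ligand = toy.ligand.transformed(final.rotation, final.translation)
        final_complex = Structure.concatenate([toy.receptor, placed_ligand])
        fp_y = fingerprint_residue(final_complex, (["R"], ["L"]), ("L", 536))
        fp_l = fingerprint_residue(final_complex, (["R"], ["L"]), ("L", 539))
        report["fingerprint_stage"] = {
            "Y536": fingerprint_report(fp_y),
            "L539": fingerprint_report(fp_l),
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        if out_dir is not None:
            _write_report(report, Path(out_dir) / "structural_report.json")
        raise
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_report(report, out / "structural_report.json")
        write_pdb(final_complex, out / "final_complex.pdb")
        loops.clustering_report(selection).to_csv(out / "loop_clusters.tsv",
                                                  sep="\t", index=False)
    return report


def run_quantification_pipeline(config: PipelineConfig,
                                measurements=None,
                                out_dir: str | Path | None = None) -> dict:
    """CTCF table, SuperPlot summaries and two-group comparisons.

    Without supplied measurements, a synthetic two-group image dataset with
    the configured effect ratio is generated and measured through the standard
    ROI path.
    """
    if measurements is None:
        measurements, _ = synth.gen_ctcf_dataset(
            effect_ratio=config.effect_ratio, n_control=config.n_control,
            n_treatment=config.n_treatment, seed=config.seed,
        )
    summaries = summarize_superplot(measurements)
    groups = sorted(summaries)
    report: dict = {
        "config_hash": config.config_hash(),
        "groups": {
            g: {
                "n_cells": s.n_cells,
                "mean_ctcf": float(round(s.mean, 2)),
                "sd_ctcf": float(round(s.sd, 2)),
                "n_replicates": s.n_replicates,
                "mean_of_replicate_means": float(round(s.mean_of_replicate_means, 2)),
                "sd_of_replicate_means": (float(round(s.sd_of_replicate_means, 2))
                                          if np.isfinite(s.sd_of_replicate_means)
                                          else None),
            }
            for g, s in summaries.items()
        },
    }
    if len(groups) == 2:
        control, treatment = groups[0], groups[1]
        a = np.array([m.ctcf for m in measurements if m.group == control])
        b = np.array([m.ctcf for m in measurements if m.group == treatment])
        if len(a) >= 2 and len(b) >= 2:
            t_res = compare_groups(a, b, test="t")
            u_res = compare_groups(a, b, test="mannwhitney")
            report["comparison"] = {
                "control": control,
                "treatment": treatment,
                "t_statistic": float(round(t_res.statistic, 3)),
                "t_p_value": float(t_res.p_value),
                "mannwhitney_p_value": float(u_res.p_value),
                "fold_change": float(round(t_res.fold_change, 3)),
                "percent_change": float(round(t_res.percent_change, 1)),
                "percent_change_rounded": int(t_res.percent_change_rounded),
            }
        else:
            report["comparison_skipped"] = "a group has fewer than 2 cells"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_report(report, out / "quantification_report.json")
        measurements_table(measurements).to_csv(out / "measurements.tsv",
                                                sep="\t", index=False)
    return report


def scan_motifs_report(sequences, alignment=None, ref_id=None,
                       region=None, phi_set="LIMFV",
                       y_threshold=0.8, phi_threshold=0.8) -> list[dict]:
    """Motif scan (plus conservation when an alignment is given) as JSON rows."""
    from .sequences import score_motif_conservation

    rows = []
    for seq in sequences:
        hits = scan_yxxphi(seq, phi_set, region)
        if alignment is not None and (ref_id is None or seq.id == ref_id):
            profiles = [score_motif_conservation(alignment, seq.id, h, phi_set)
                        for h in hits]
            for c in classify_motifs(profiles, y_threshold, phi_threshold):
                rows.append({
                    "seq_id": seq.id, "y_position": c.hit.y_position,
                    "window": c.hit.window,
                    "y_fraction": round(c.profile.y_fraction, 3),
                    "phi_fraction": round(c.profile.phi_fraction, 3),
                    "conserved": c.conserved,
                })
        else:
            for h in hits:
                rows.append({"seq_id": seq.id, "y_position": h.y_position,
                             "window": h.window})
    return rows


def _write_report(report: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=str) + "\n")
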