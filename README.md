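# pendock

Modelling how a transmembrane cargo presents a tyrosine-based sorting signal
to the clathrin adaptor AP-2, and quantifying the consequences for its
cell-surface abundance.

## The scientific problem

The anion exchanger SLC26A4 (pendrin) is internalised from the apical
membrane of endolymphatic-sac epithelial cells by clathrin-mediated
endocytosis. Cargo recruitment into clathrin-coated pits is driven by the μ2
subunit of the AP-2 complex, which recognises **YXXΦ** motifs (a tyrosine,
two arbitrary residues, and a bulky hydrophobic residue Φ ∈ {L, I, M, F, V})
in cytosolic cargo tails. Establishing such an interaction computationally
involves a chain of analyses, each implemented here as a library module:

1. **Motif discovery** (`pendock.sequences`) — scan the cytosolic C-terminal
   region for YXXΦ motifs and score the conservation of the Y and Φ columns
   across an ortholog alignment (gaps count against conservation; default
   thresholds 0.8).
2. **Structural availability** (`pendock.structure`, `pendock.loops`) — a
   motif can only engage μ2 if it is solvent-exposed. The motif-bearing loop
   is remodelled: conformers with Ramachandran-favoured backbones are closed
   onto the anchors by cyclic coordinate descent, clustered with the Daura
   exclusive algorithm at RMSD cutoffs {1.5, 2, 2.5, 3, 3.5, 4} Å, the
   cutoff chosen as *the lowest with the highest top-cluster occupancy*, and
   the representative maximising the minimum relative SASA of the four motif
   residues (Shrake–Rupley, probe 1.4 Å, Gly-X-Gly normalisation) is kept if
   it exceeds 60 %.
3. **Restraint-guided docking** (`pendock.docking`) — Cα–Cα distances
   between the motif residues (Y, Φ) and the μ2 pocket residues
   (174, 176, 203, 401, 420, 422, 423) are extracted from a reference
   complex and imposed as flat-bottom restraints (optional ±0.3 Å
   half-width). Poses funnel through generate → re-rank → cluster
   (2000/500/200 at study scale), in two runs: stage A from random rigid
   starts, stage B seeded by stage A's selected model. The final model is
   the best-energy member of the most populated pose cluster. The scoring
   function is a documented surrogate
   (`total = restraint + clash + 0.1·contact`), not a force field.
4. **Interaction fingerprints** (`pendock.fingerprint`) — hydrogen bonds
   (heteroatom ≤ 3.5 Å), hydrophobic contacts (apolar carbons ≤ 4.5 Å, with
   an explicit apolar-typing table so an arginine's aliphatic chain is
   distinct from its guanidino group) and cation-π interactions (cation
   group centroid to aromatic ring centroid ≤ 6 Å).
5. **CTCF statistics** (`pendock.quantify`) — corrected total cell
   fluorescence, `CTCF = IntDen − Area × mean(background)`, per-cell from
   images + ROI masks; SuperPlot summaries (per-replicate means, mean ± SD
   of those means); Student's t, Mann-Whitney, one-way ANOVA + Tukey HSD;
   fold and percent change.

`pendock.synth` generates every input class with known ground truth —
sequences with planted motifs, ortholog families with controlled column
conservation, a toy motif-peptide/pocket complex with a known bound pose,
loop ensembles with planted cluster structure, and fluorescence images with
planted cell intensities — so the whole pipeline is testable offline.

## Worked example

```bash
python analysis/01_scan_motifs.py
python analysis/02_loop_ensemble.py
python analysis/03_dock_complex.py
python analysis/04_fingerprint.py
python analysis/05_ctcf_stats.py
```

Output of the docking + fingerprint steps (synthetic toy system, seed 11):

```
stage A: best model energy -13.42, ligand RMSD to planted pose 0.07 A
stage B final model: energy -13.64 (restraint 0.158, clash 0.003, contact -138),
RMSD to planted pose 0.27 A
  motif tyrosine (L:536): {'hbond': 2, 'hydrophobic': 3, 'cation_pi': 2}
    hbond       -> ASP176  (OH/OD1, 2.7 A)
    hbond       -> LYS203  (NZ/OH, 3.0 A)
    hydrophobic -> PHE174  (CZ/CD1, 3.8 A)
    hydrophobic -> TRP421  (CH2/CE2, 4.2 A)
    hydrophobic -> ARG423  (CD/CZ, 3.6 A)
    ...
  motif leucine (L:539): {'hbond': 0, 'hydrophobic': 3, 'cation_pi': 0}
```

The staged funnel re-finds the planted bound pose to 0.27 Å, and the docked
tyrosine is coordinated exactly as the pocket was designed: hydrogen bonds
to the aspartate and lysine, aromatic packing against the phenylalanine and
tryptophan, and both an aliphatic contact and a cation-π interaction from
the arginine. The CTCF step prints

```
printed endogenous group means: fold 1.63, percent increase 63%
simulated experiment (planted 63% effect, DMSO n=70 vs dynasore n=73):
  percent increase 72.0% (t p=1.28e-11, Mann-Whitney p=7.63e-11)
```

— the percent change computed from the printed group means is exactly 63 %,
while a single simulated experiment at these group sizes scatters around the
planted effect with a standard error of roughly 7 percentage points.

There is also a CLI (`pendock scan-motifs|sasa|superpose|loop-ensemble|dock|
fingerprint|ctcf|compare|simulate|run-all`) wrapping the same functions.

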