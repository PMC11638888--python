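# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of the pipeline, and what the synthetic test systems do and
do not establish about real data.

## Motif scanning and conservation

A YXXΦ hit at position *p* requires Y at *p* and a Φ-set residue at *p*+3,
both inside the scanned region; overlapping hits are all reported. The Φ set
defaults to {L, I, M, F, V}, the canonical bulky-hydrophobic set for
tyrosine-based sorting signals; it is configurable because usage in the
literature varies (W and Y are sometimes admitted). `X` matches neither Y
nor Φ. Numbering is 1-based with inclusive ranges, so positions printed for
full-length proteins (e.g. Y536) can be used directly; fragments carry an
explicit `numbering_offset`.

Conservation of a motif over an alignment is the fraction of rows with Y in
the reference tyrosine column and a Φ-set residue in the reference Φ column.
Gap characters stay in the denominator and count as non-conserved — the
conservative convention for sparse ortholog panels. Default thresholds are
y = Φ = 0.8, which separates motifs conserved in ≥ 8 of 10 family members
from motifs degraded in 3 or more. Alignments are consumed (aligned FASTA or
Clustal), never computed.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral point set, 960 points and
probe 1.4 Å by default. Van der Waals radii are a single Bondi-style protein
set (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å); unknown elements fall back
to 1.70 Å with a warning. The sphere-point set is oriented in a
molecule-fixed principal-axes frame (signs fixed by coordinate skewness), so
SASA is invariant under rigid transforms of the structure rather than merely
approximately so.

Relative per-residue SASA is normalised by the theoretical Gly-X-Gly maxima
of Tien et al. (2013). This is the denominator behind the "accessible above
60 %" selection rule; chain-terminal residues of isolated fragments can
legitimately exceed 1 because the tripeptide reference assumes two peptide
neighbours. Waters and non-standard residues are excluded unless requested.

## Loop remodelling

Loop conformers are sampled on a fixed scaffold: backbone φ/ψ drawn from
three Ramachandran-favoured bins (α at (−63, −43) ± 12°, β at
(−120, 130) ± 20°, ppII at (−75, 150) ± 15°, weights 0.35/0.40/0.25), ideal
Engh–Huber-like bond geometry, closure onto the N/CA/C atoms of the residue
following the loop by cyclic coordinate descent (closed-form optimal angle
per bond; tolerance 0.10 Å RMSD over the three closure atoms, giving
per-atom anchor agreement within 0.3 Å). Side chains come from a staggered
rotamer set (χ ∈ {−60, 60, 180}). Conformers clashing with the scaffold
(heavy-atom distance < 2.0 Å, anchors excluded) are resampled. Sampling is
deterministic for a fixed seed. This sampler deliberately replaces a
statistical-potential loop modeller; any generator satisfying the
closure/clash contract is interchangeable here.

Ensembles are clustered with the exclusive greedy algorithm of Daura et al.:
the member with the most neighbours within the RMSD cutoff seeds a cluster,
it and its neighbours are removed, and the procedure recurses. RMSD is
measured on loop Cα after superposition on a rigid-core selection (the
scaffold is shared in generated ensembles, making that fit the identity).
Ties in neighbour count break to the lowest member index; clusters are
ordered by descending size. The cutoff is selected from the ladder
{1.5, 2, 2.5, 3, 3.5, 4} Å as the smallest whose top-cluster occupancy
(fraction of members in the largest cluster) attains the ladder maximum.
"Occupancy" is interpreted as largest-cluster fraction; the alternative
(count of clusters above a size) is not used.

Among cluster representatives, the conformer maximising the *minimum*
relative SASA over the four motif residues is selected, with a pass/fail
flag against the 60 % threshold; a most-populated-cluster policy is also
available. Study-scale pools are 10,000 models; tests and the analysis
scripts run 25–200, which exercises every rule while keeping runs in
seconds to minutes.

## Restraint-guided docking

Restraints are Cα–Cα distances between the cargo motif residues (Y, Φ) and
the adaptor pocket residues, measured live in a reference complex —
distances are never hard-coded. The flat-bottom half-width is 0 by default
with ±0.3 Å as a protocol option.

The surrogate energy is
`total = w_r·restraint + w_c·clash + w_a·contact` with weights
(1.0, 1.0, 0.1): restraint = Σ max(0, |d − target| − tol)² over restraints
plus, when an active/passive interface specification is given, a
HADDOCK-style ambiguous term max(0, d_min − 5 Å)² per active residue (d_min
= minimum heavy-atom distance to the partner's interface atoms); clash =
Σ (2.5 − d)² over heavy-atom pairs below 2.5 Å; contact = −1 per
inter-partner heavy-atom pair within 5 Å. A violation below 1e−9 Å is
treated as zero so self-extracted restraints score exactly 0 on their
reference. The energy depends only on interatomic distances and is therefore
invariant under shared rigid transforms.

Pose generation: stage A draws uniformly random ligand orientations
(quaternion sampling) with the ligand centre placed within 15 Å of the
active-residue centroid; stage B perturbs a seed pose (default 8° / 1 Å
Gaussian amplitudes; zero amplitudes score the seed as-is, a fixed point).
Each start is minimised in three steps: (1) Levenberg–Marquardt least
squares on the restraint residuals over the 6 rigid degrees of freedom;
(2) a scan of rotations about the axis through the two most separated
restrained ligand Cα atoms (15° steps), because distance restraints to a
small number of ligand sites leave that rotation essentially unconstrained;
(3) a short Nelder–Mead refinement of the full energy. The funnel keeps the
`n_scored_kept` best of `n_generated`, re-ranks them with the same surrogate
energy — a deliberate divergence from an explicit-solvent rescoring stage —
and clusters the `n_clustered` best on ligand-Cα RMSD (Daura, cutoff 5 Å).
The final model is the lowest-energy member of the most populated cluster(s)
(ties allowed; the qualifying-size fraction is configurable). Backbone
flexibility is approximated by docking against several loop conformers and
pooling the pose sets.

Default pipeline tolerance is 0 Å rather than ±0.3 Å: both protocols exist
(and both are tested), but under the surrogate energy the flat bottom lets
the contact reward pull the final model ~3 Å from a planted pose, so the
exact-restraint protocol is the default for pose reproduction. With it, the
staged A→B funnel at 200 models per stage recovers the planted pose of the
synthetic pocket system to well under 1 Å in ≥ 90 % of seeded runs.

## Interaction fingerprints

Hydrogen bonds: donor/acceptor heteroatom pairs within 3.5 Å, using explicit
side-chain donor and acceptor tables plus backbone N (donor) and O
(acceptor); with explicit hydrogens a ≥ 120° donor-H-acceptor angle filter
applies, otherwise the criterion is distance-only (the usual case for models
built here). Hydrophobic: residue pairs with apolar-carbon contact within
4.5 Å; the apolar typing table is explicit (e.g. Arg: CB, CG, CD only) so an
arginine's aliphatic chain is distinguishable from its charged guanidino
group. Cation-π: cationic group centroid (Arg guanidino = NE/CZ/NH1/NH2,
Lys NZ, His ring only when flagged protonated) to aromatic ring centroid
(Phe/Tyr six-ring, Trp benzene ring, His ring) within 6.0 Å. One interaction
per residue pair per kind, represented by its closest atom pair, matching
how per-residue networks are narrated. The defaults follow common structural
practice; the geometric criteria used to draw any particular published
figure are generally unstated, so counts on a docked model are indicative
rather than exact expectations.

A chemical note observed on the synthetic pocket: a lysine ammonium donating
to a tyrosine hydroxyl necessarily sits within ~5.5 Å of the ring centroid
(the hydroxyl is only 2.8 Å from the ring edge), so it is also reported as a
cation-π partner under the 6 Å default. This is geometry, not a detector
artefact.

## CTCF and statistics

`CTCF = IntDen − Area × mean(background)`, with IntDen the raw pixel sum
over the cell ROI, area in pixels, intensities in arbitrary units, and the
background mean taken over the union of user-supplied background ROIs (the
synthetic generator places three). CTCF is linear in image intensity and
invariant to adding a constant to all pixels. It may legitimately be
negative for cells dimmer than the background.

SuperPlot summaries report per-group cell-level mean ± SD (n−1 denominator),
per-replicate means and the mean ± SD of those means; both levels are always
computed and labelled with the replicate count, since printed ± values are
sometimes cell-level and sometimes replicate-level. Two-group comparisons
default to the unpaired two-sided pooled-variance Student's t test (Welch by
flag) with Mann-Whitney as the non-parametric companion; fold change is the
ratio of group means (treatment/control) and percent change is
100·(fold − 1), rounded to the nearest integer when reported as a headline
number. Multi-group comparisons use one-way ANOVA with Tukey HSD
(Tukey-Kramer for unbalanced groups) via `scipy.stats`. Two groups of
identical constant values compare with p = 1 by convention.

## Synthetic data: what it does and does not show

Generators are pure functions of their parameters and seed (NumPy PCG64; one
stream per generator call).

- **Sequences** draw background residues from the non-tyrosine alphabet, so
  every motif is planted and the regex oracle enumerates the full truth.
- **Ortholog families** apply i.i.d. substitutions (no indels by default)
  with explicit per-column overrides for planting exact conservation
  fractions.
- **The toy complex** places a YKNL peptide in an engineered pocket whose
  residues are numbered and typed like the μ2 tyrosine-binding pocket
  (F174, D176, K203, V401, K420, W421, V422, R423) with an alanine shell
  providing concavity. Its bound pose is clash-free, restraint-consistent
  and reproduces the canonical interaction networks of the tyrosine and the
  hydrophobic residue. It is a geometric stand-in — pose recovery on it
  demonstrates the correctness of the restraint/funnel machinery, not
  docking accuracy on real adaptor complexes.
- **Offset loop ensembles** translate the loop along one axis so pairwise
  RMSD equals the offset difference exactly, giving fully calibrated cluster
  structure for the clustering and cutoff-rule checks (closure is
  deliberately not maintained there). The calibrated cutoff ensemble splits
  its major state into two tight lobes 2.3 Å apart so the
  lowest-cutoff/highest-occupancy rule must return 2.5 Å from the standard
  ladder.
- **Images** are background + hard-edged disks + Gaussian noise — no PSF, no
  cell-shape variation. In the two-group dataset, per-cell amplitudes are
  lognormal (CV 0.35) around group means with ratio 1.63 and radii uniform
  in 10–16 px; at the study's group sizes (70/73 cells) a single experiment
  estimates the percent change with a standard error of about 7 percentage
  points, so simulated values in the high 50s to low 70s are expected around
  the planted 63 %.

Passing tests on these systems establishes the algorithms and their selection
rules; they say nothing about cryo-EM loop ensembles, force-field quality or
microscope noise beyond the stated models.

## Numerical conventions

Ties in Daura clustering break to the lowest member index; cluster ordering
is (size desc, representative index asc). `select_cutoff` treats occupancies
within 1e−12 as equal. Kabsch superposition rejects < 3 pairs and collinear
selections, and always returns a proper rotation. PDB output is fixed-width
with MODEL/ENDMDL for ensembles; parsing keeps the highest-occupancy altloc
and the first model unless all models are requested. Seeds derived from a
user seed stay below 2³¹.
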