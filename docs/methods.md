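# Methods

## Problem setting

Human RPE65 functions as a homodimer; its dimer-mediating sequence (DMS) and
the surrounding β-sheet carry a cluster of missense variants of uncertain
significance (VUS).  The package assesses such variants along two independent
tracks — a consensus of sequence-based variant-effect predictors, and
post-processing of coordinate ensembles from molecular-dynamics simulations
of mutant–WT dimer models — and combines them into a four-level
pathogenic-potential class.  The MD simulations themselves (system
preparation, minimisation, heating, µs-scale production) are upstream of this
artifact: it consumes their output as multi-model coordinate ensembles.

## Consensus track (ConPath)

**Binarization.**  Predictors emit either binary pathogenic/neutral calls or
raw scores.  Scored tools are binarized at their published cutoffs
(0 for Eigen, Eigen-PC, SNPs3D, INPS-sequence, PROST; 0.4 for Integrated
FitCons; 0.5 for REVEL, VEST4, DANN, MutPred2, PON-P2; 0.75 for MVP; 20 for
CADD and CADD_hg19; 50 for SuSPect) under the convention *score ≥ cutoff ⇒
pathogenic*.  The boundary case is not documented by the tools themselves;
the ≥ convention matches common usage (e.g. "CADD ≥ 20") and a per-tool
strict-inequality override is exposed.  Tool names are canonicalised through
an alias map ("Mut. Assesor", "MutationAssessor" → "Mut. Assessor") so
matrices and benchmark rows always join.

**Benchmarking.**  Against a labelled set (reference cohort: 27 pathogenic,
3 benign — the class imbalance is a property of the available ClinVar
labels, not a choice), each tool's calls yield TP/TN/FP/FN with pathogenic
as the positive class.  Precision, specificity, recall and accuracy follow
the standard formulas; metrics with a zero denominator are reported as
undefined rather than 0.  Metrics are kept at full precision internally and
rounded half-up to 2 decimals only in reports.

**Panel selection.**  Tools enter the voting panel when recall ≥ 0.78 and
specificity ≥ 0.67.  The comparison is made at the 2-decimal reporting
precision: on a 3-negative benchmark a specificity of 2/3 prints as 0.67 and
must satisfy a 0.67 threshold, which a raw-fraction comparison would reject
by 3·10⁻³.  Selection preserves input order; an empty selection is legal and
logged.

**ConPath score.**  The score is the count of panel tools calling the
variant pathogenic.  With the reference 19-tool panel, ≥ 10 is a pathogenic
consensus (≤ 9 neutral).  For other panel sizes the default threshold is the
strict majority ⌊n/2⌋+1, overridable, and every report carries the panel
size.  Missing panel predictions are a hard error by default; an opt-in
policy counts them as neutral votes (conservative toward non-pathogenicity)
with a logged warning.

## Structural track

**Superposition.**  Frames are superposed by the least-squares optimal rigid
transform (proper rotation + translation, computed via the Kabsch solution
as implemented in scipy's `Rotation.align_vectors`).  Fits require ≥ 3
non-collinear atoms.  The fit selection stands in for the positional
restraints of the production simulations: fitting on the restrained external
Cα set and measuring the DMS Cα RMSD without refit reproduces the frame of
reference the upstream analysis used.

**RMSD / RMSF.**  The per-frame RMSD is measured over the DMS Cα selection
after fitting; the summary statistic is the mean over the second half of the
frames ([N/2, N)).  RMSF is the root-mean-square deviation of each Cα from
its window-mean position after superposition, reported per residue.
Averaged structures are plain coordinate means of superposed frames and are
flagged unminimised (no force-field relaxation is applied).  "Last µs"
windows default to the final third of frames.  Model residue numbering is
translated to hRPE65 numbering by a fixed offset (default 277: model 98–102
↔ hRPE65 375–379).

**Hydrogen bonds.**  The upstream analysis names H-bonds but no geometric
criteria, so conventional ones are adopted and exposed as configuration:
donor–acceptor heavy-atom distance ≤ 3.5 Å and donor–H–acceptor angle ≥
135°.  Donors are N/O atoms with a covalently attached hydrogen (attachment
inferred at ≤ 1.25 Å within the residue); acceptors are N/O atoms;
intra-residue pairs are excluded.  Topologies without hydrogens fall back,
with a logged warning, to a heavy-atom-only criterion of 3.3 Å (the fallback
can be disabled).  A residue-pair occupancy counts a frame once regardless
of how many atom pairs qualify, so bidentate contacts are not double
counted; the atom-level breakdown is retained.  A water bridge requires one
water oxygen within the distance criterion of a polar atom of *each* residue
in the same frame — two different waters do not bridge.  Salt bridges
(contacts between charged side-chain N/O groups) are tagged but treated like
any other H-bond by the alert rule.  Side-chain heavy-atom contact fractions
(4.5 Å cutoff) are reported for hydrophobic environments but never feed the
interaction alert.

**Interaction alert.**  Native WT interactions are the direct contacts with
occupancy ≥ 0.50.  A native pair is *maintained* in the mutant when some
direct contact between the same residue pair reaches occupancy ≥
max(0.50, WT − 0.20); the alert fires when ≥ 1 native pair involving the
mutated residue is lost.  The floor/drop calibration (0.50 / 0.20) is the
unique simple rule consistent with every quantified WT→mutant judgment in
the reference analysis (e.g. 0.55→0.52 maintained; 0.80→<0.50 disrupted;
0.90→0.60 disrupted); it is configurable.

**Structural alert.**  Fires when the mutant's second-half mean DMS RMSD is
≥ 1.5 Å (the WT reference sits near 1.0 Å), OR when ≥ 3 consecutive
residues show mutant RMSF ≥ 2.0 Å while the WT profile stays < 1.0 Å there.
The reference cohort's flagged variants showed both signatures, so whether
the original criterion was AND or OR is not observable; OR is adopted as the
more sensitive screen, and the evidence records which criterion fired.

## Classification

Each variant carries three flags: structural, interaction, ConPath
(score ≥ threshold).  The class is a pure function of the alert count —
3 → HPPV, 2 → MHPPV, 1 → MLPPV, 0 → LPPV — with no weighting between alert
types (a borderline consensus score such as 9 is surfaced in the evidence
text only).  The high-confidence subset is the union of LPPV and HPPV:
variants where all three lines of evidence agree.  Variants lacking ensemble
data are reported with unknown flags but never classified.

## Synthetic data

The generator produces the two input families the pipeline needs.

*Benchmarks*: cohorts with a configurable pathogenic:benign split (default
27:3, matching the reference cohort) and per-tool (sensitivity, specificity);
each call is an independent Bernoulli draw.

*Ensembles*: a ~60-residue two-chain poly-alanine toy dimer with polar side
chains (serine/asparagine/lysine/glutamate/tryptophan at fixed positions,
mimicking the W402–E404–S307B interface-bridge topology) plus a small water
reservoir.  Frames are the reference plus independent per-residue **rigid**
Gaussian displacements with per-coordinate scale σ/√3, so the per-atom RMSF
converges to the per-residue target σ and intra-residue geometry (donor–H
bonds) is preserved.  Prescribed contacts place the acceptor atom in bonded
geometry (distance U[2.7, 3.3] Å, angle U[150°, 180°]) with per-frame
probability equal to the target occupancy and otherwise well outside it
(U[4.5, 6.0] Å); water bridges move a dedicated water oxygen to ~2.9 Å from
both partners or back to the reservoir.  The placement bands sit safely
inside/outside the detection criteria, so the generator's realized Bernoulli
fraction *is* the ground-truth occupancy, and the manifest records both the
target and the realized value.

What the toy ensembles deliberately lack: frame-to-frame autocorrelation,
solvent beyond the bridging waters, realistic covalent geometry and any
force-field physics.  Tests that pass on them certify the estimators
(occupancy counting, RMSF/RMSD bookkeeping, alert logic) — not the realism
of any MD protocol.  Occupancy-recovery tests therefore check two separate
things: that the measurement reproduces the generator's realized draw
exactly, and that draws recover the target within binomial confidence
bounds.

The packaged reference fixtures are transcriptions of the published
evaluation: the 19-tool benchmark statistics with their implied confusion
counts, the two P/N call matrices, the alert table, the WT/mutant
residue-pair occupancies and the RMSD/RMSF summary magnitudes.  Where the
source text gives only a phrase ("more than 50%", "almost 100%") a single
representative value on the stated side of the threshold was fixed once;
these values are inputs, not measurements, and are labelled as
transcriptions in the fixture docstrings.

## Numerical choices and limitations

* Rounding for reports is decimal half-up at 2 decimals; raw fractions are
  never overwritten.
* Selections use inclusive 1-based residue ranges (`A:70-125:CA`); Å
  throughout.
* Ensembles written as multi-model PDB keep 3-decimal coordinates; the
  writer/reader round-trip is exact to that precision.
* Test and acceptance problem sizes (hundreds to 2000 frames, toy dimers of
  ~400 atoms, benchmark cohorts up to 3000 variants) were chosen so the full
  suite completes in seconds while keeping sampling errors well below the
  tolerances asserted.
* The H-bond geometric criteria are conventional defaults, not extracted
  from any upstream tool configuration; analyses sensitive to them should
  sweep the thresholds.
* The interaction alert is H-bond-based by design: purely hydrophobic
  packing changes (e.g. valine→phenylalanine repacking) appear only in the
  contact-occupancy report and never fire the alert.
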