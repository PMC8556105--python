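# Methods

## Problem and model

Metal ions cross membranes through transmembrane proteins (TMPs), and the
residues that coordinate them are functionally critical, yet TMP structures
are hard to obtain experimentally.  `metalsite` therefore predicts metal-ion
binding residues from sequence-derived information only.  The model is a
two-stage cascade of random forests over sliding-window samples:

* **Stage 1 (detection).** A binary classifier separates residues binding
  any of 24 recognized metal species from non-binding residues.  Its output
  probability is the fraction of tree votes; a residue passes the gate at
  probability ≥ 0.5 (configurable).
* **Stage 2 (assignment).** Seven one-vs-rest scorers — K, Ca, Na, Zn, Mg,
  Hg, and "Others" (the remaining 18 species pooled) — are trained on
  binding residues only, each class against all other binding residues.
  Gated residues receive the argmax class; exact ties resolve to the earlier
  class in the fixed order above.  One-vs-rest scores are reported raw
  (unnormalized); they are not a probability simplex.

Stage 2 trains on *true* binding residues by default rather than stage-1
positives: this decouples the stages during training, so a stage-1 error
cannot corrupt the class scorers' training distribution.  A
`stage2_on_predictions` mode couples them for users who want the deployed
gate reflected in training.

Residues binding several metals simultaneously carry all of their classes
and contribute one stage-2 sample per class — one-vs-rest treats classes
independently, so this is consistent.

## Feature space

Five channels, concatenated in the fixed order PSSM | PCP | rASA | Zcoord |
TOPO (the ablation-ladder order):

* **PSSM** (20): log-odds block of a PSI-BLAST ASCII profile, columns in
  PSI-BLAST order (A R N D C Q E G H I L K M F P S T W Y V).  Only the
  log-odds block is used — that is what "evolutionary information"
  conventionally denotes; the weighted-percentage block is discarded.
  Values are fed raw: random forests are insensitive to monotone scaling.
* **PCP** (553): numerical amino-acid property scales parsed from an
  AAindex1 flat file.  Missing ("NA") values are mean-imputed across the
  defined amino acids, which is deterministic and preserves each scale's
  units.  No canonical list of 553 accessions ships with the package: the
  reader takes an optional accession list (and an `expected_count` check) so
  any curated subset can be plugged in; by default all usable entries are
  retained.  Residue letters outside the 20-letter alphabet receive the
  per-property mean (a neutral value on each scale).
* **rASA** (1): relative solvent accessibility in [0, 1].
* **Zcoord** (1): signed distance to the membrane centre plane in Å.
* **TOPO** (3): one-hot three-state topology (inside / membrane / outside),
  parsed from TMHMM-style segment lists or per-residue TSV.

All on-disk coordinates are 1-based inclusive; in memory everything is
0-based half-open.

**Windows.** Sample *i* stacks rows *i*−(w−1)/2 … *i*+(w−1)/2 (row-major).
Default w = 9: binding pockets for small ions are compact, and window
lengths well below the ~17 appropriate for bulky ligands (ATP/NAD-class)
are expected to be optimal; a sweep helper over {3, 5, …, 17} is provided
since the best w is dataset-dependent.  Terminal overhang is zero-padded by
default — zero rows are distinguishable from real residues — with
repeat-edge padding available for comparison.

**Scaling** (optional, off by default for forests) fits per-column z-score
or min-max transforms on training chains only; zero-variance columns pass
through with a warning.

## Imbalance and validation

Binding residues are a few percent of a chain, so stage-1 training keeps
every positive window and draws 5 negatives per positive uniformly without
replacement (seeded, order-shuffled).  Undersampling happens *inside each
training fold only*; validation folds keep natural balance, because metrics
on rebalanced data would be inflated.

Cross-validation partitions **chains**, not residues: windows of adjacent
residues share most of their rows, so residue-level splits leak.  Default
k = 10.  Per-fold seeds derive from the master seed via `SeedSequence`.
The cross-validated score is the across-fold mean (reported with its SD).

Metrics: ACC, SPE, SEN, MCC (defined 0 when any denominator factor
vanishes; SPE/SEN with empty denominators are reported missing, never 0)
and trapezoidal ROC AUC with tied scores grouped at one threshold.  The
implementation is checked in the tests against scikit-learn and against the
Mann–Whitney U identity AUC = U/(n₁n₂).

## Curation

From PDB-format structures: a residue is labeled binding when **any heavy
atom lies strictly within 3.5 Å of a metal atom** — the first-coordination-
shell heuristic; the cutoff is configurable and the boundary is exclusive.
Chains are kept when longer than 50 residues (strict) with at least one
binding residue.  Redundancy is removed at 40% pairwise identity, either
from a CD-HIT `.clstr` file (one representative per cluster: longest, ties
by id) or a greedy longest-first fallback using global alignment identity
over the shorter sequence (CD-HIT's convention).  Non-standard residues
(e.g. MSE) map to parent letters via the chemical-component table; an
unmappable residue becomes X and never carries a positive label.

## Synthetic study conditions

The fixture generator emulates every input dialect so the whole pipeline
runs and tests offline.  Defaults — the package's study conditions — are 30
chains of 60–120 residues, a 5% binding rate spread uniformly over the seven
classes, and a 3σ effect planted in the PSSM channel; chains shorter than
real TMPs and a binding rate at the high end of realistic keep desk-scale
runs statistically well-powered.  The PCP fixture table has 12 properties
by default (column count is a layout property, tested once at full width).

Signal model: background PSSM scores are rounded draws from N(0, σ=2)
clipped to ±16.  A binding residue of class *k* receives +effect·σ on all
20 columns (detection signal) plus +2·effect·σ on its class's two signature
columns (columns 2k, 2k+1; disjoint across classes), so detection and class
assignment are comparably separable at a given effect size.  Optional
signal in the other channels: composition bias toward class-preferred
letters (PCP), an rASA shift, membrane-centred Z-coordinates, and a
membrane-state bias (TOPO).  At effect 0 labels are independent of every
feature — the permutation null.

What the generator does **not** emulate: real profile correlations along the
sequence, realistic amino-acid composition or binding-site chemistry
(letters are uniform unless PCP signal is requested), and realistic membrane
geometry.  Passing tests therefore demonstrate that the pipeline's
machinery — labeling, encoding, rebalancing, the cascade, the metrics — is
correct and well-calibrated, not that the published feature set attains any
particular accuracy on real TMPs.

Toy PDB structures place metals on the z-axis of a residue's CA at scripted
distances (residues 6 Å apart), so the scripted distance is exactly the
minimum heavy-atom distance and cutoff boundary cases are exact.

## Numerical and design notes

* Random-forest defaults: 500 trees, unlimited depth, √d features per
  split; all exposed, and the classifier is pluggable (any sklearn-style
  factory) for SVM / naïve Bayes / AdaBoost comparisons.
* The model archive records the feature layout (channels, widths, window,
  padding); prediction refuses a mismatched layout with a diff.
* Prediction TSVs format floats at fixed precision, making runs
  byte-reproducible under a fixed seed.
* Binding-domain FASTA export pads terminal overhangs with X so every
  record has full window length; X is excluded from the 20-letter counts,
  which makes the position-frequency matrix rebuilt from the export equal
  the directly computed one.
* `scripts/acceptance.py` uses 10-fold CV on the default 30-chain study,
  5 recovery seeds and 10 null replicates — sizes chosen to keep the full
  report under a few minutes on one CPU while leaving the statistics
  well-resolved.

## Known limitations

* The external predictors that produce real inputs (PSI-BLAST profiles,
  topology, rASA, Z-coordinates) are not run here; their output files are
  parsed.  Results on real chains inherit those tools' errors.
* The 553-property AAindex subset is configuration, not shipped content.
* The greedy identity fallback is O(n²) alignments — fine for hundreds of
  chains, slow beyond that; supply a CD-HIT `.clstr` file instead.
* Stage-2 classes with fewer than two positive (or negative) binding
  samples are disabled with a warning rather than trained.
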