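# Methods

`epiwin` predicts which residues of an antigen are antibody-interacting
(conformational B-cell epitope residues) from the primary sequence alone.
This note records the model, the parameters that matter, what the synthetic
data does and does not emulate, and the numerical and design choices made
where the procedure was genuinely open.

## Problem and ground truth

In an antigen–antibody complex structure, an antigen residue is defined as
*antibody-interacting* when at least one of its atoms lies within 4 Å
(inclusive) of any antibody atom — the benchmark interface definition used
to score structure-based epitope predictors. `structure.label_from_complex`
implements this rule over user-named antigen and antibody chains:

- **Heavy atoms only.** Hydrogens (and deuteriums) are excluded: the crystal
  structures such labels come from rarely resolve them, and including them
  would make labels depend on per-file refinement practice.
- **HETATM excluded on both sides** (no glycan, ligand or water atoms): the
  rule concerns residues of the antigen and atoms of the antibody protein.
- **Alternate locations:** the highest-occupancy conformer only (Biopython's
  default selection).
- **Comparison is `<=`**, so a contact at exactly 4.0 Å is interacting.
- **Sequence = resolved residues.** The per-chain sequence is read from the
  ATOM records in chain order; residues without coordinates are skipped with
  a warning. SEQRES reconciliation (aligning the deposited full sequence to
  the resolved residues) is deliberately not attempted — it needs alignment
  machinery disproportionate to this module, and labels for unresolved
  residues would be guesses either way.

`structure.generate_complex_fixture` builds synthetic two-chain complexes
with a *known* interface for testing: antigen residues on a widely spaced
line, one antibody contact atom placed at an exact chosen distance from each
planted epitope residue. Coordinates are jittered on a 0.25 Å grid, which is
exactly representable both in the PDB fixed-point columns and in binary
floating point, so a contact planted at exactly the cutoff stays exactly at
the cutoff after a write/parse round trip.

## Patterns and encodings

Every residue yields one window ("pattern") of odd length W (5–21; default
19) centered on it; the sequence is padded with (W−1)/2 dummy `X` per side
so terminal residues have full windows. A pattern is positive iff its
central residue is interacting. Three encodings:

- **BPP** (binary profile): one-hot, 21 values per position (20 amino acids
  + `X`), alphabetical order with `X` last → dimension 21·W.
- **PPP** (physico-chemical profile): 5 values per position, in order Parker
  hydrophilicity, Karplus–Schulz flexibility, Grantham polarity, a
  Ponnuswamy-series polarity/hydrophobicity scale, Kolaskar antigenicity →
  5·W. Raw published values ship in `data/property_scales.tsv` and are
  min–max normalized to [0,1] across the 20 residues at load; `X` receives
  each property's column mean so padding is neutral. Note: the shipped
  fourth scale is the Ponnuswamy et al. (1980) average-surrounding-
  hydrophobicity tabulation; if you prefer a different polarity index, pass
  any TSV with the same columns to `PropertyScaleTable.from_tsv`.
- **CPP** (composition profile): percent amino-acid composition of the
  window, comp(i) = 100·R_i/N — 20 values regardless of W. The denominator
  N counts all W positions *including* padding `X` (which occupies no bin),
  so windows overlapping a terminus sum to less than 100; this keeps the
  vector a fixed-scale function of a fixed-length window and makes terminal
  location itself visible to the classifier. An X-free window always sums
  to exactly 100.

Training sets come in two regimes: **balanced** (all positives plus an
equal-size uniform random sample of negatives, seeded) and **realistic**
(all patterns, natural ~2% positive prevalence). Exact duplicate window
strings can be collapsed (`deduplicate_patterns`); duplicates carrying
contradictory labels are dropped entirely and reported, since a
contradictory training point is noise.

## Classifier

A support vector machine in SVM-light parameter vocabulary: `t 2 g γ`
selects the RBF kernel, `t 1 d n` a polynomial kernel, `c` the margin
trade-off, and the cost factor `j` multiplies the penalty on positive-class
training errors (mapped to an asymmetric class weight, `class_weight={1: j}`
in scikit-learn's SVC). `j = 1` is the balanced-regime default; `j > 1`
compensates class imbalance in realistic-regime training. The optimizer
tolerance is 1e−3 with a 200 MB kernel cache; non-convergence surfaces as a
warning. Training is deterministic given the data order and configuration.

The reference window-19 composition model uses `t 2 g 0.01 j 1 c 1` on the
percent-scale CPP features. Decision scores are thresholded at Thr (score ≥
Thr is an epitope call, inclusive); the shipped default Thr = −0.3. For
reporting, scores map to a 0–9 confidence scale via the empirical deciles of
the *training* decision scores, stored with the model: 0 = rarest chance of
being epitopic, 9 = most probable. The decile map is monotone and clamps
out-of-range scores; it is a ranking aid, not a calibrated probability.

## Evaluation

Threshold-dependent measures, with a positive call iff score ≥ Thr:

    Sen = 100·TP/(TP+FN)        Spe = 100·TN/(TN+FP)
    Acc = 100·(TP+TN)/(TP+TN+FP+FN)
    MCC = (TP·TN − FP·FN) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN))

MCC uses the standard square-rooted denominator; when any factor is zero the
value is defined as 0 and flagged. ROC AUC (trapezoidal over all distinct
scores, ties stepped simultaneously) is the threshold-independent summary.

Cross-validation is 5-fold: a seeded random partition into near-equal sets
(sizes differ by ≤1), each used once for testing. The out-of-fold scores are
pooled, a threshold grid (default −2.0…+2.0, step 0.1) is scanned, and the
operating point Thr\* minimizing |Sen − Spe| on the pool is selected —
sensitivity/specificity balance is the selection rule throughout. Per-fold
metrics at Thr\* are averaged (headline numbers); pooled-count metrics and
pooled AUC are also reported. Two split units are supported:

- `pattern` (default): patterns are partitioned individually — the classical
  protocol for residue-window classifiers.
- `antigen`: all windows of one antigen stay in one fold.

**Window-overlap leakage.** The two split units answer different questions.
Adjacent windows of the same epitope patch share W−1 of W residues, and the
composition encoding is almost invariant to a one-residue shift; with
pattern-level folds, near-duplicates of every test window sit in the
training folds. Consequences, both measured by `scripts/acceptance.py`:
(i) pattern-level scores are strongly optimistic — on synthetic data with a
genuine composition signal the CPP model reaches MCC ≈ 0.9 pattern-level
versus ≈ 0.25–0.3 antigen-held-out; (ii) pattern-level evaluation shows
skill even when the generator plants *no* signal (MCC ≈ 0.88 at zero
enrichment — pure memorization), whereas antigen-held-out evaluation is
correctly at chance (MCC ≈ 0.04, AUC ≈ 0.53). Shift-robustness also partly
explains why composition beats the one-hot encoding so decisively under the
pattern-level protocol: a one-residue shift leaves CPP nearly unchanged but
misaligns every BPP block. Any no-skill (null) check in the test suite
therefore uses antigen-held-out folds; protocol-faithful comparisons of the
encodings use pattern-level folds. Users measuring expected performance on
new antigens should use `split_unit="antigen"`.

## Synthetic data

`simulate.generate_antigens` draws labeled antigens in which a minority of
residues form sequence-local epitope patches whose composition is enriched
for the charged/polar residues over-represented at antibody interfaces
(C, D, E, K, N, Q, R, W, Y). Defaults — the conditions under which the
pipeline checks run — are 200 antigens of 150 residues, epitope fraction
0.08, patch lengths 5–15, uniform background (1/20 each; natural
frequencies can be supplied), and enrichment δ = 0.25: inside a patch, a
total probability mass of δ is moved from non-enriched onto enriched
residues, each proportionally to its background frequency (uniform
background: enriched-set mass 0.45 → 0.70). δ = 0 is the null condition;
feasible δ is bounded by the background mass outside the enriched set
(0.55 for uniform). Patch placement is uniform without overlap, re-drawn up
to 1000 attempts then an error; the final patch may be shortened to hit the
target count. Everything is deterministic under the config seed.

What the generator deliberately does **not** emulate: real conformational
epitopes are sequence-discontinuous patches on the folded surface. The
simulator plants sequence-local runs because a window-based predictor only
ever sees local sequence composition — local enrichment is precisely the
signal the method assumes — so discontinuity adds nothing testable at the
window level. Passing pipeline tests therefore demonstrate that the
implementation recovers a planted local-composition signal and shows no
skill without one; they say nothing about performance on real antigens,
where the strength of the composition signal, sequence redundancy, and the
conformational scattering of epitopes all differ.

## Numerical and interface choices

- Non-standard residue letters are sanitized deterministically with a logged
  warning: B→N, Z→Q, U→C, anything else (J, O, …) → X; lowercase uppercased.
- Positions are 1-based in every file and message.
- All tables are TSV, UTF-8, `#` comments allowed; encoded sets can be
  exported in SVM-light sparse format.
- Balanced negative subsampling, fold partitions, and simulation are all
  driven by explicit seeds; CLI runs write a JSON manifest (parameters,
  seeds, input checksums, version, timestamp) next to their outputs.
- Ties at the decision threshold are called positive (inclusive ≥,
  consistent with the inclusive 4 Å rule); stated in output headers.
- The operating-point selector breaks ties toward the lowest threshold.
- Problem sizes in the test suite and acceptance script (200 antigens × 150
  residues; ≈4800 balanced window-19 patterns per condition) were chosen so
  a full encoding comparison cross-validates in about a minute on one CPU
  while keeping binomial sampling error on MCC/AUC well below the margins
  being asserted.

## Known limitations

- Homology redundancy reduction (e.g. clustering antigens at 40% identity)
  is an external preprocessing step; the package consumes whatever FASTA it
  is given.
- The 0–9 scale is decile-based ranking, not a probability.
- Pattern-level cross-validation numbers must not be read as generalization
  to unseen antigens (see window-overlap leakage above).
- mmCIF, multi-model NMR ensembles, and automatic antibody-chain detection
  are out of scope; single-model PDB only, chains named explicitly.
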