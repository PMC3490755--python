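# Methods

## Problem and data model

An RNA-binding protein chain is represented at two resolutions: the full
amino-acid sequence (FASTA) and the solved coordinates of a protein–RNA
complex (PDB format). A residue is an **interface residue** when at least one
of its atoms lies within a cutoff of any atom of the bound RNA; the atoms of
all RNA chains in the complex are pooled. The cutoff defaults to 5.0 Å
(3.5 Å is a common alternative and changes results materially — both are
plain parameters here). By default *all* atoms present in the file
participate in the distance computation; a heavy-atom-only policy is
available for comparison with interface definitions stated in terms of heavy
atoms.

Residues present in the sequence but missing from the coordinates are
labeled non-interface (they cannot be observed in contact). Two dataset
variants follow: the **sequence** variant keeps every residue, the
**structure** variant keeps only solved residues. Interface counts are
identical between the variants by construction; the non-interface counts
differ by exactly the number of unsolved residues. Chains enter a benchmark
when they have ≥ 40 residues, ≥ 3 interface residues, and the complexed RNA
is ≥ 5 nucleotides long (all thresholds inclusive).

Mapping solved residues onto the full sequence first tries a unique exact
substring match of the concatenated solved one-letter string; failing that, a
global alignment with identity scoring is used in which gaps in the solved
string (unsolved spans) are cheap and gaps in the full sequence are heavily
penalized; ≥ 95% identity over the aligned solved residues is required.
Modified residues map to their parent amino acid through a fixed table
(MSE→M etc.); unmapped residues become 'X'. Only the first MODEL of
multi-model files is read; altloc conflicts keep the highest-occupancy
conformer; waters and ions are excluded.

## Feature encodings

Six encodings cross three per-residue channels with two window types.

* **Channels.** Identity: a 21-symbol one-hot (20 amino acids + 'X') per
  window position. PSSM: the 20 log-odds scores of the position, each
  squashed by the logistic function y = 1/(1+e^(−x)). Smoothed PSSM: raw
  scores are first summed over a window of w neighboring positions
  (default w = 3, i.e. positions i−1..i+1; out-of-range neighbors contribute
  zero) and then normalized. Summation happens on the *raw* scores, before
  normalization; the alternative order (normalize then sum) would bound each
  term and is deliberately not used, so the two can be diffed if needed.
* **Windows.** Sequence windows take the target plus (W−1)/2 flanking
  residues each side in chain order (default W = 25 → 500 PSSM features or
  525 identity features). Spatial windows take the target plus the W−1
  nearest solved residues by centroid distance (centroid = heavy-atom mean;
  ties broken by ascending sequence position). W counts the *total* window
  size including the target in both cases, so all encodings share one
  dimension law. Spatial windows are defined only on solved residues, so
  spatial encodings require the structure variant.
* **Padding.** Positions outside the chain (or missing neighbors) encode as
  'X' in the identity channel and as the neutral logistic midpoint 0.5 in
  the PSSM channels; for smoothing sums the pad contributes raw 0. An
  optional auxiliary scalar channel (e.g. externally predicted
  accessibility) appends one value per window position, with pad value 0.

## Classifiers

**Naïve Bayes.** Class priors are training frequencies. Feature columns whose
training values are all in {0,1} get Bernoulli tables with the Laplace
add-one estimator, (k+1)/(n+2); all other columns get per-class Gaussian
mean/variance with a variance floor of 1e−9. Scoring is the log posterior
ratio, computed in log space; the predicted label is 1 when the ratio is
≥ 1 (ties go to the interface class, following the ≥ convention). The choice
of Gaussians for continuous features is a design decision; supervised
discretization is a known alternative and is not implemented.

**SVM.** The standard soft-margin problem with either the polynomial kernel
(x·z+1)^p or the RBF kernel exp(−γ‖x−z‖²). Defaults p = 1 (linear), γ = 0.01,
C = 1.0, used without any tuning. The quadratic program is delegated to
scikit-learn's SVC (solver tolerance 1e−6, well inside the 1e−3 KKT contract
the tests check against an independent dual solver); the fitted model is kept
as its dual expansion (support vectors, α·y, bias), which makes decision
values and JSON serialization self-contained. Ranking scores are raw signed
decision values, not calibrated probabilities. Before SVM training the
majority class is undersampled to the minority count with a seeded generator;
test data are never balanced. Naïve Bayes is trained unbalanced by default.

## Evaluation

Cross-validation is **sequence-based**: whole chains are permuted with a
seeded generator and dealt round-robin into k folds (default k = 5), so train
and test sets are disjoint at the sequence level; window-based splitting is
deliberately unsupported. Metrics use the precision-style convention common
in this problem area: Specificity = TP/(TP+FP) (precision),
Sensitivity = TP/(TP+FN) (recall), F = 2·P·R/(P+R),
MCC = (TP·TN−FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). Degenerate cases: zero
positive predictions give Specificity 1 and Sensitivity = F = MCC = 0; any
vanishing denominator gives F or MCC 0.

**Residue-based aggregation** pools confusion counts over the proteins of a
fold, computes fold metrics, and averages over folds; fold ROC/AUC are
computed on the fold's pooled scores (a globally pooled AUC across folds is
reported alongside, since fold-averaged and globally pooled AUC can differ).
**Protein-based aggregation** computes metrics per protein, averages within
the fold, then across folds; per-protein AUC is undefined for single-class
proteins, which are excluded from the fold average and counted. AUC is the
Mann–Whitney statistic with half credit for ties, identical to the
trapezoidal area under the threshold-swept ROC curve; ROC thresholds sit at
distinct score values, so instance order never matters.

Methods are compared across datasets by **tie-averaged ranks**: per dataset,
rank 1 is best and tied scores share the mean of their positions; ranks are
then averaged across datasets. No significance test is attached (rank-based
omnibus tests need more datasets than a typical three-benchmark comparison
provides).

## Surface residues and the post-filter

Surface residues have relative solvent accessibility strictly greater than
5%. Accessibility is taken from a precomputed NACCESS-style `.rsa` table when
supplied; otherwise a built-in Shrake–Rupley estimator samples each atom's
solvent sphere (vdW radius + 1.4 Å probe) at 960 quasi-uniform golden-spiral
points over the heavy atoms of the isolated chain, and per-residue areas are
divided by theoretical per-residue maxima (Tien-style values) to give
percentages. Numeric parity with NACCESS is explicitly not promised; the
estimator converges to its own dense-sampling limit within 2% at the default
point count. The post-filter demotes predicted interface residues that are
known buried (surface False) to non-interface; unknown surface status leaves
predictions untouched. The filter only ever removes positive predictions.

## Synthetic benchmarks

The generator emulates the statistical structure of the real inputs, not
their physics. Each chain is a pseudo-backbone of CA atoms at 3.8 Å spacing
with two jittered side atoms (≤ 0.4 Å); a pseudo-RNA strand sits 4.0 Å above
a contiguous interface patch. The geometry guarantees exact label recovery at
the 5.0 Å cutoff: the nearest non-patch residue is at least
√(3.8² + 3.6²) ≈ 5.23 Å from any RNA atom even at maximal jitter. Patch
placement allows clipping at chain ends (≥ 3 residues remain, matching the
inclusion filter) so that every residue has near-equal marginal probability
of being interface; without this, termini would be systematically
non-interface and window padding would leak label information even with no
profile signal. PSSM raw scores are N(0, σ²) with a mean shift δ added to 5
fixed columns at interface positions (defaults σ = 1, δ = 2). Defaults:
20 chains of 50–70 residues, patch length 8, seeded per-artifact generators
derived from one master seed (byte-identical reruns).

What passing tests on these benchmarks do **not** show: robustness to real
evolutionary profiles (correlated columns, composition biases), real
interface geometry (discontiguous patches, multiple RNA contacts), homology
between chains, or NACCESS-parity accessibility. They do show that every
pipeline stage — parsing, mapping, labeling, windowing, training, fold
bookkeeping, aggregation — is wired correctly and that the signal path from
profile columns to cross-validated AUC behaves monotonically in δ.

## Numerical choices and problem sizes

Logistic normalization uses the overflow-safe expit. The variance floor in
Gaussian NB is 1e−9. Fold seeds derive deterministically from the run seed
(seed·1009 + fold). Null-band cross-validation checks run on an 84-chain
benchmark (~5,000 residues): at 20 chains the fold AUC of a no-signal run is
dominated by within-chain correlation of overlapping windows (observed
spread ≈ ±0.1), while at ~5,000 residues it concentrates within ±0.05 of
0.5. Planted-signal checks use the default 20-chain conditions.

## Known limitations

* PDB fixed-column dialect only; no mmCIF, no gzip, no NMR multi-model
  averaging (first model only).
* PSI-BLAST is not run; profiles are consumed as ASCII files (the standard
  three-iteration, E ≤ 0.001 profiles in this literature).
* Redundancy reduction between chains (e.g. 30% identity filtering) is
  accepted as a precomputed chain list, never computed.
* The built-in accessibility estimator is a Shrake–Rupley sampler, not a
  NACCESS reimplementation; supplied `.rsa` files take precedence.
* No probability calibration, ensembles, or hyperparameter search — the
  classifiers are deliberately run at fixed defaults.
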