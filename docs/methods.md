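# Methods

This note documents the models, conventions and numerical choices behind
`t3pks`, and what the synthetic test bed does and does not demonstrate
about real data.

## Pairwise alignment and identity

All sequence comparison rests on one affine-gap dynamic program (Gotoh's
three-state formulation, numba-compiled) used in two modes:

* **local** (Smith–Waterman) for mining, with the BLAST default costs —
  BLOSUM62, gap open 11, extend 1;
* **global** (Needleman–Wunsch) for network identity and active-site
  mapping, with gap open 10, extend 1.

A gap of length *k* costs `open + k·extend`.  **Percent identity** is
identical aligned columns divided by total alignment length, *gap columns
included in the denominator*; this is stricter than matched-column-only
conventions and is stated so users can compare values from other tools.
Tie-breaking in the traceback is fixed (match state preferred over a gap
in the second sequence, over a gap in the first; extension preferred over
restart in local mode), making alignments — not just scores — fully
deterministic.  Because the tie-break is orientation-dependent,
`pairwise_identity` canonicalises argument order so the reported value is
exactly symmetric.  The kernel's scores are verified in the test suite
against Biopython's `PairwiseAligner` and its alignments column-for-column
against an independent pure-Python implementation of the same
conventions.

Network identity uses global rather than a BLAST-score proxy (as some SSN
web tools do) because it is symmetric, parameter-light and reproducible;
the 57%/80% cutoffs users know from such tools are treated here as plain
identity fractions.

## Similarity networks

Sequences with pairwise identity strictly above `repnode_threshold`
(default 0.95) are collapsed single-linkage — i.e. connected components
of the >threshold graph — into representative nodes; the longest member
(ties: lexicographically smallest id) represents each.  Edges connect
representatives at identity ≥ `cutoff`; clusters are connected components
of that graph, numbered 1..K by descending member count with ties broken
by the smallest member id, so numbering is stable across runs.  All-vs-all
alignment is O(n²); an optional 4-mer prefilter (skip pairs sharing <2%
of 4-mers) engages automatically above 2,000 sequences.

## Active-site mapping

Each candidate is aligned globally to a user-supplied reference (the
documented default for this enzyme family is MsCHS, UniProt P30074, not
bundled; tests use a synthetic reference with the triad planted at
164/303/336).  Reference numbering is anchored to reference columns:
insertions in the query shift nothing, deletions read as `-`, and the gap
symbol is a first-class logo category — for queries far below ~40%
identity to the reference, a gap often means "numbering transfer is
uncertain here" rather than a physical deletion, and the logos make that
visible.  Triad substitutions are reported in `H303D` notation.  A
profile or MSA-based transfer would be a reasonable alternative;
pairwise-to-reference was chosen for its independence from alignment
software and its per-sequence determinism.

## Featurization

Enzyme vectors are the mean over residues of a per-residue feature
matrix.  The built-in `fallback-physchem` embedder maps each residue to
eight z-scored physicochemical scales (Kyte–Doolittle hydropathy,
side-chain volume, residue mass, pI, charge at pH 7, aromaticity,
polarity, Chou–Fasman helix propensity) plus a 21-letter one-hot, so the
pooled vector is property means plus amino-acid composition (dim 29).
It is deterministic, needs no download, and is what every test uses.
Transformer protein language models plug into the same registry;
requesting `prottrans-x5` without torch/transformers installed degrades
to the fallback with a logged warning.  Mean pooling is the only pooling
offered, deliberately.

Substrates are parsed from SMILES by RDKit and fingerprinted as binary
MACCS keys (167 bits) or Morgan/ECFP (default radius 2, 2048 bits,
binary).  Canonicalisation makes bits independent of input atom order.
A pair vector is the concatenation enzyme ++ substrate; feature sets
carry their (embedder, fingerprint, params) tags and downstream code
refuses to mix mismatched sets.

## Classifiers and evaluation protocol

Decision tree, random forest (100 trees) and MLP (one hidden layer of
100 ReLU units, adam, early stopping with patience 10) from scikit-learn.
Features are standardised inside every fit (scaler fitted on the training
split only); this is essential for the MLP on mixed continuous/binary
concatenations and harmless for the trees.  No class reweighting by
default (training prevalence ~43% is near-balanced); balanced weights are
a config option.

One evaluation **run** = one stratified k-fold cross-validation (default
5 folds) under its own seed, scored on the pooled out-of-fold
predictions; the default 20 repeats yield 20 runs and the reported
mean ± sd is **across repeats** (the report records this axis).  Model
comparison is a paired two-sided Wilcoxon signed-rank test on per-run F1
(zero-split tie handling; paired t-test below 6 runs; p = 1 when the
vectors are identical), at α = 0.05.  Deployment trains
`n_prediction_runs` (default 100) models on the full training set with
distinct seeds derived from one base seed, averages predicted
probabilities per pair, and binarises at a 0.5 decision threshold.
Stratification requires every class to have at least as many members as
folds; violating datasets are rejected with a message rather than
silently re-stratified.

## Position importance

Residue columns (from active-site extraction) are one-hot encoded and a
random forest is fitted; a position's score is the drop in training-set
accuracy when all of its indicator columns are shuffled together (grouped
permutation, 3 permutations by default), averaged over bootstrap
replicates of the enzyme set (default 10).  `stability` is the fraction
of replicates keeping the position in the top decile.  Constant columns
score exactly 0 by construction.  This is a descriptive association
measure, not a causal claim, and columns correlated with family
membership will share credit with a true determinant — the planted-rule
recovery tests therefore use a single-family design where columns vary
independently of the label.

## Synthetic test bed

`SyntheticSpec` defaults define the study conditions: 3 families of
(11, 10, 10) members, length 380, within-family point-mutation rate 0.05
(pairwise identity ≈ 0.90), ancestor divergence rate 0.41 from a common
root (between-family identity ≈ 0.35), triad columns frozen, and a
specificity column (197) carrying one diagnostic residue per family.
The 11-substrate panel (5 aromatic, 3 unsaturated aliphatic, 3 saturated
aliphatic carboxylic acids) and the default rule — V accepts
non-aromatic substrates, F aromatic ones, A only substrates with a
non-aromatic C=C — give exactly 146 of 341 pairs active (43%).  Observed
labels are the rule XOR Bernoulli(label-noise rate); exact rule labels
are kept as ground truth.  Substitutions are uniform over the 19
alternatives with no indels or rate heterogeneity, so divergence
statistics are exactly binomial and easy to test.

What passing tests therefore show: the machinery recovers planted
structure (families, rules, determinant columns) under controlled
identity and noise.  What they do not show: performance on real enzymes,
where homology has indels and phylogenetic autocorrelation, activity
labels derive from detection-limited assays, substrate space is chemically
broader, and informative features require learned embeddings rather than
physicochemical summaries.  Published headline accuracies from comparable
real-data studies depend on the specific enzyme sequences and multi-GB
language-model embeddings and are out of this package's desk scope.

## Pipeline determinism

The driver derives each stage's seed by hashing (global seed, stage
name), so toggling one stage never shifts another's randomness.  All
artefacts are UTF-8 text with fixed float formatting, and the manifest
records a sha256 per output; reruns with identical config are
byte-identical, which the test suite asserts.

## Problem sizes

Default test and acceptance workloads use the study-shaped dataset
(31 enzymes × 11 substrates), 20-repeat cross-validation, 100-seed
importance repetitions at reduced profile width (30–40 columns), and a
reduced pipeline fixture (3 × 4 enzymes) for the byte-identity check —
sizes chosen to exercise every code path at full statistical fidelity
while keeping a complete run in the minutes range on one CPU.
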