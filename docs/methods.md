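# Methods

This note records the modelling choices behind `mtqsar`: what is
computed, which defaults were chosen where the protocol left room, and
what the synthetic benchmark does and does not establish.

## Curation

Raw records are (compound id, SMILES, IC50, target id). Only exact IC50
values are accepted; qualified values (">", "<") should be excluded
upstream, and concentration units are declared per file (molar default,
nM supported).

*Structure standardization.* The parent structure is the largest
covalent fragment by heavy-atom count (ties broken by lexicographically
smallest canonical SMILES), with formal charges neutralized where
chemically possible (RDKit `Uncharger`). The operation is idempotent;
unparseable SMILES are skipped and logged, never fatal in batch mode.

*Labelling.* pIC50 = −log10(IC50 in mol/L). The activity threshold is
chosen from a candidate grid — by default 0.5-unit steps over
[4.0, 9.0] pIC50 — as the argmin of class imbalance |#active −
#inactive|, ties broken toward the smallest threshold (favouring the
active class). Records exactly at the threshold are active (≥
convention). These two conventions are stated once here and asserted
throughout the tests.

*Duplicates.* Records sharing a canonical SMILES collapse to one with
the median pIC50 (robust to wild assay values). If the duplicate
measurements straddle the chosen threshold and their median lies within
±0.3 pIC50 of it, the compound's label is considered ambiguous and the
compound is dropped (logged as a rejection). Datasets smaller than 40
compounds after curation are flagged `underpowered`: panels routinely
show that their smallest activity set produces the weakest classifiers.

## Features

*Compounds.* MACCS keys (166 bits; RDKit's unused slot 0 dropped) and
ECFP6 count fingerprints (circular environments of radius 3 hashed to
1024 slots; occurrence counts, not bits; hash collisions accepted).
Both are invariant to SMILES respelling because they are computed from
the parsed molecule.

*Proteins.* Sequence-only descriptors: amino-acid composition (20),
dipeptide composition (400), optional tripeptide composition (8000), and
composition/transition/distribution (CTD) descriptors over the seven
canonical three-class physicochemical groupings (hydrophobicity,
normalized van der Waals volume, polarity, polarizability, charge,
secondary structure, solvent accessibility): 21 + 21 + 105 = 147 values.
The default family set (AAC + dipeptide + CTD, 567 features) omits
tripeptides, which dominate runtime and add little for small panels;
enabling them approaches the full ~8.6k-descriptor inventory of
sequence-descriptor toolkits. Transition frequencies are
direction-insensitive and normalized by L−1; distribution descriptors
report the positions (as % of sequence length) of the first, 25%, 50%,
75% and last residue of each class, with all-zero blocks for absent
classes.

*Normalization and reduction.* The protein descriptor matrix over the
panel is min–max normalized to [0, 1] (constant features map to 0;
out-of-fit values are clipped) and PCA-projected. The configured target
dimension is 150 components, but the effective dimension is capped at
min(150, n_sequences − 1, n_features) — with a 15-protein panel the
descriptor matrix has rank at most 14, so the protein block carries at
most 14 components. The cap is stated rather than hidden: with random
or few sequences, the protein block is essentially a learned target
identity encoding, not a biophysical embedding.

*PCM assembly.* A PCM feature vector is the compound fingerprint
followed by its target's projected protein block; the compound block is
identical across targets, the protein block differs.

## Classifiers

Four learners × two fingerprints per target, plus the same four learners
× two PCM feature kinds pooled over the panel. Canonical vote order:
RF_MACCS, RF_ECFP6, SVM_MACCS, SVM_ECFP6, KNN_MACCS, KNN_ECFP6,
NN_MACCS, NN_ECFP6, then the same eight `_protein` PCM names.

Hyperparameter defaults (all overridable per algorithm in
`SuiteConfig.hyperparameters`):

| learner | default | notes |
|---|---|---|
| RF | 500 trees, unlimited depth | raw count fingerprints |
| KNN | k = 5, Euclidean | min–max scaled features |
| SVM | RBF, C = 1, scale gamma | probabilities via a calibrated decision function (`CalibratedClassifierCV`, single model); scaled features |
| NN | one hidden layer of 100 ReLU units, ≤ 500 iterations (Adam) | scaled features |

Tree ensembles see the count fingerprints raw; distance- and
gradient-based learners see min–max scaled features so no slot dominates
the metric or kernel. Each classifier votes 1 when its positive-class
probability reaches 0.5.

*Splits and validation.* Per target: stratified 80/20 train/test split
(per-class test counts are rounded, so the class proportions are within
one item of the global fraction). Cross-validation uses stratified
k-fold (k = 5) inside the training partition only; the fold allocator
deals each class's remainder to the currently smallest folds so that
both per-class counts and overall fold sizes differ by at most one.
CV metrics pool the out-of-fold predictions of all folds into a single
confusion table (rather than averaging per-fold metrics), which keeps
MCC well-defined for small folds; the choice is recorded in the report
metadata column `partition = "cv"`. The scaler and projection of the
protein block are fitted once on the panel and frozen; fingerprint
scalers are fitted inside each training set (and inside each CV fold),
so no test information leaks into training.

*Determinism.* A single master seed fans out to split, fold and model
seeds via a stable CRC32 hash of the component name, so a suite build is
reproducible end-to-end and two pipeline runs under one seed produce
byte-identical reports.

## Multivoting ensemble

A compound–target query collects 16 binary votes; the pair is called
active iff vote_count ≥ cutoff, with default cutoff 9 (the accuracy
optimum of the sweep on pooled held-out data). The ≥ convention is
deliberate and exposed as configuration: an inclusive threshold at 9 is
the reading consistent with a 1–16 sweep whose optimum is reported *at*
9. Because the positive sets at successive cutoffs are nested, SE is
non-increasing and SP non-decreasing in the cutoff — asserted on every
sweep. The sweep's `AUC` column is the balanced accuracy (SE + SP)/2 at
each cutoff, the conventional single-number summary of such a table on a
near-balanced test set; the orthodox ROC AUC obtained by treating the
0–16 vote count as a ranking score is reported separately as
`vote_auc`.

Batch prediction accepts SMILES lists, `.smi` or SDF files, caps a batch
at 1000 molecules (configurable), and reports unparseable molecules in a
rejection table instead of failing. Active calls induce a bipartite
compound–target graph; `degree_stats` reports node degrees, the all-node
median degree and the two bipartite means, and
`filter_by_median_degree` keeps compounds whose degree strictly exceeds
the all-node median (targets are always retained; the strictness means a
perfectly uniform network filters to no compounds, which is logged
rather than special-cased). The median is computed over compound and
target nodes only; grouping nodes (e.g. herbs aggregating ingredients)
are not part of the degree statistics.

## Synthetic benchmark

The generator fabricates what a curated multi-target activity panel
looks like, without any external data:

- **Targets**: random 200–600-residue sequences over the 20-letter
  alphabet, each assigned a distinct signature ring fragment from a
  16-fragment pool (benzene through quinoxaline). Signatures may nest
  chemically (benzene embeds in naphthalene), and ground truth honestly
  uses substructure semantics, so one compound can be a true positive
  for several targets.
- **Compounds**: 2–4 chainable aliphatic decoration fragments
  concatenated into a valid SMILES, with the target's signature fragment
  spliced in for ~half the compounds. Decorations are acyclic, so
  signature containment is unambiguous.
- **Potency**: pIC50 ~ Normal(μ0 + δ, σ) for signature carriers and
  Normal(μ0, σ) otherwise, with μ0 = 4.5, δ = 3, σ = 0.5. At these
  defaults the probability that noise pushes a compound across the
  midpoint threshold is ≈ 2·(1 − Φ(δ/2σ)) ≈ 0.27%, so per-model held-out
  AUCs land high while leaving enough disagreement for the ensemble
  cutoff to matter.

What passing tests on this benchmark shows: the curation chain, feature
plumbing, suite structure, vote bookkeeping, metric arithmetic and
determinism are correct, and the ensemble recovers a planted, learnable
signal. What it does not show: performance on real chemistry. Real
activity sets have correlated scaffolds, assay heterogeneity, activity
cliffs and meaningful protein similarity, none of which the generator
emulates; its random sequences in particular mean PCM models can exploit
the protein block only as a target identity code.

## Problem sizes used in the checks

The automated checks run at sizes chosen to exercise the full structure
while staying desk-sized: the structural count check builds the full
15-target × 200-compound suite; signal recovery uses the default
benchmark (5 × 400); the interior-optimum check repeats a 2-target ×
100-compound build over 20 seeds; determinism re-runs a 2 × 40 pipeline
twice. The acceptance script reports, for each quantity, the problem
size it was computed at.

## Known limitations

- No hyperparameter search; defaults are sensible, not tuned.
- No applicability-domain estimation; a vote count is not a calibrated
  probability.
- Charge neutralization covers the common protonation states handled by
  RDKit's `Uncharger`; exotic salts or organometallics may survive.
- Stereochemistry is preserved as given but not normalized or enumerated.
- The PCM protein block is only as informative as the descriptor matrix
  rank allows (≤ n_targets − 1 components).
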