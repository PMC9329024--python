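# mtqsar

Multitarget QSAR and proteochemometric (PCM) modelling of chemical–protein
interactions (CPI), with a calibrated multivoting ensemble and
compound–target network export.

## The problem

Polypharmacology questions — *which of these proteins does this molecule
hit?* — are naturally posed over a panel of targets at once. Given curated
bioactivity data (compound, SMILES, IC50) for each target in a panel,
`mtqsar`:

1. **Curates** each target's records into a binary classification set:
   salts stripped to the parent structure, duplicates collapsed to the
   median activity, IC50 converted to pIC50 = −log10(IC50 mol/L), and an
   activity threshold chosen from a candidate grid so the active/inactive
   classes come out as balanced as the data allow.
2. **Trains 8 classifiers per target** — the cross of four learners
   (random forest, k-nearest neighbours, RBF SVM, one-hidden-layer neural
   network) with two compound fingerprints (166-bit MACCS keys and
   1024-slot ECFP6 counts, radius 3) — plus **8 pooled PCM classifiers**
   shared across the panel, whose features concatenate the fingerprint
   with a min–max-normalized, PCA-reduced protein sequence descriptor
   block (amino-acid/dipeptide composition and CTD descriptors). A panel
   of T targets yields 8·T + 8 classifiers (128 at T = 15).
3. **Evaluates** with a stratified 80/20 split and 5-fold
   cross-validation, reporting SE, SP, Q (accuracy), MCC and ROC AUC:

   SE = TP/(TP+FN)  SP = TN/(TN+FP)  Q = (TP+TN)/N
   MCC = (TP·TN − FN·FP) / √((TP+FN)(TP+FP)(TN+FN)(TN+FP))

4. **Predicts by multivoting**: each compound–target pair receives 16
   binary votes (8 per-target + 8 PCM models); the pair is called an
   interaction when at least `cutoff` votes are positive. Sweeping the
   cutoff 1→16 trades sensitivity against specificity monotonically; the
   default cutoff 9 sits at the accuracy optimum of that sweep.
5. **Exports networks**: active calls over a molecule batch become a
   bipartite compound–target graph (SIF / GraphML), with degree
   statistics and a median-degree promiscuity filter.

Because real panels require activity-database exports, the package ships
a synthetic chemogenomics generator (`mtqsar.synthetic`) that fabricates
multi-target benchmarks with planted, fragment-based structure–activity
signal; every stage is testable end-to-end without downloads.

## Worked example

```python
from mtqsar import CPIModel, generate_benchmark

bench = generate_benchmark(n_targets=3, n_compounds_per_target=150, seed=42)
results = CPIModel(bench.datasets, bench.sequences).fit(seed=42)
print(results.summary())
```

The summary header reports the suite structure:

```
Chemical-protein interaction model suite
============================================
targets: 3   classifiers: 32 (24 per-target + 8 PCM)
vote cutoff: 9 of 16   master seed: 42
```

Mean held-out ROC AUC of the per-target models, by algorithm:

```
KNN    0.960
NN     0.970
RF     0.968
SVM    0.981
```

(the planted signal is strong, so all four learners rank the held-out
compounds almost perfectly). The ensemble cutoff sweep on the pooled
test partitions shows the canonical trade: sensitivity falls and
specificity rises with the cutoff, with a broad accuracy plateau:

```
 cutoff     Q    SE  SP   MCC
      1 0.966 0.933 1.0 0.935
      9 0.966 0.933 1.0 0.935
     14 0.955 0.911 1.0 0.914
     16 0.854 0.711 1.0 0.741
```

Prediction for new molecules returns the 16 named votes and the call:

```python
pred = results.predict([("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
                        ("decoy", "CCCC")], cutoff=9)
print(pred.table[["compound_id", "target_id", "vote_count", "call"]])
```

```
compound_id target_id  vote_count     call
   caffeine       T01          13   active
   caffeine       T02          11   active
      decoy       T01           0 inactive
```

Caffeine's fused N-heterocycle resembles the aromatic signature
fragments planted for these synthetic targets, so it collects most of
the 16 votes; the aliphatic decoy collects none.

The same workflow is available from the shell:

```bash
mtqsar simulate --targets 5 --compounds 400 --seed 1 --out bench/
mtqsar train --activities bench/activities.csv --fasta bench/targets.fasta \
             --seed 1 --out suite/
mtqsar sweep --suite suite/ --activities bench/activities.csv --out sweep.csv
mtqsar predict --suite suite/ --molecules query.smi --cutoff 9 --out pred.csv
mtqsar network --predictions pred.csv --out net.sif
```

or as a single reproducible pipeline: `mtqsar run --config pipeline.yaml`.

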