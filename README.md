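# afpkit

A toolkit for predicting **antifreeze proteins (AFPs)** — the ice-binding
proteins that let fish, insects, plants and microbes survive subzero
temperatures by depressing the freezing point of their body fluids (thermal
hysteresis). Because AFPs are structurally and sequentially heterogeneous,
sequence-only classifiers need feature representations that capture
composition, local order and evolutionary signal at once. afpkit implements
such a pipeline end to end for researchers building or evaluating AFP
predictors: feature encoding, feature selection, classifier training and a
complete evaluation protocol, plus a synthetic benchmark generator so the
whole pipeline runs and is testable without PSI-BLAST or any database
download.

## The method

Given a protein of length *L* (and, for the profile descriptors, its
PSI-BLAST position-specific scoring matrix *A* ∈ ℝ^(L×20)), four encoders
produce a named feature vector:

- **GAAC** (5 features): frequencies of five physicochemical residue groups,
  F(G_k) = n(G_k)/n for the aliphatic (AGLIMV), negatively charged (DE),
  aromatic (FWY), positively charged (HRK) and uncharged (CNPQST) groups.
- **DPC** (400 features): dipeptide composition, the frequency of each of
  the 20×20 ordered adjacent residue pairs, normalized by the L−1 windows
  so the vector sums to 1.
- **PseTS-PSSM** (60 features by default): the PSSM is sigmoid-normalized
  elementwise, f(t) = 1/(1+e^(−t)), and tri-sliced by row into blocks of
  ⌊L/3⌋, ⌊L/3⌋ and L−2⌊L/3⌋ rows; each slice contributes its 20 per-column
  means. Pseudo sequence-order correlation factors — per column, the mean
  squared difference between entries a fixed rank apart — can be appended
  per slice as an opt-in extension.
- **Sg-PSSM-ACT** (60 features by default): the same three-way split, read
  as segments; each segment contributes, per column *n* and lag,
  ACT_n = 1/(S−lag) Σ_m (A_{m,n} − μ_n)(A_{m+lag,n} − μ_n), the lagged
  autocovariance around the segment's own column mean μ_n.

Fused vectors (525 columns for all four defaults) feed **ERT-RFE**:
recursive feature elimination in which an extremely-randomized-trees
ensemble scores importance each round, the lowest-ranked features are
dropped, each surviving subset is scored by stratified cross-validated
accuracy, and the subset with maximal accuracy wins. Final models are
random forest, extremely randomized trees, or leaf-wise gradient boosting
(LightGBM) with the published configuration: max depth 8, L1 penalty
(alpha) 1, learning rate (eta) 0.1, L2 penalty (lambda) 1, 500 estimators.

Evaluation is stratified tenfold cross-validation with the confusion
pooled over folds: Acc, Sn, Sp, Precision, Recall, F-measure,
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP)), and AuROC/AuPR from
the pooled out-of-fold scores. An imbalance ablation re-runs the protocol
on seeded positive:negative subsamples (1:1, 1:2, 1:3).

## Worked example

```python
import afpkit as a

config = a.preset("strong", seed=7, n_pos=100, n_neg=100)
dataset = a.generate_dataset(config)
pssms = a.make_pssm_set(dataset, config)
matrix = a.encode_dataset(dataset, pssms)
print(f"encoded {matrix.n_records} records x {matrix.n_features} features")

trace = a.ert_rfe(matrix, step=0.25, cv_folds=5, min_features=20,
                  seed=7, n_estimators=100)
best = trace.iterations[trace.best_iteration]
print(f"ERT-RFE kept {len(trace.selected_names)} features "
      f"(inner CV accuracy {best.cv_accuracy:.4f})")

selected = a.apply_selection(matrix, trace)
report = a.cross_validate(selected, a.ModelConfig(kind="LXGB", seed=7),
                          k=10, seed=7)
print(f"Acc {report.acc:.2%}  Sn {report.sn:.2%}  Sp {report.sp:.2%}  "
      f"F {report.f_measure:.2%}  MCC {report.mcc:.4f}  "
      f"AuROC {report.auroc:.4f}  AuPR {report.aupr:.4f}")
```

prints

```
encoded 200 records x 525 features
ERT-RFE kept 20 features (inner CV accuracy 1.0000)
Acc 99.50%  Sn 100.00%  Sp 99.00%  F 99.50%  MCC 0.9900  AuROC 0.9999  AuPR 0.9999
```

The synthetic "strong" preset plants a large composition gap between the
classes and a high-signal profile, so a correct pipeline should recover a
near-perfect classifier — the numbers above are that recovery check, not a
claim about real AFP data. Selection keeps the group-composition features
(`GAAC.G1`, `GAAC.G2`, …) first, exactly where the generator put the signal.

The same steps are available from the shell:

```bash
afpkit synth --preset strong --seed 7 --n-pos 100 --n-neg 100 --out bundle/
afpkit encode --fasta bundle/sequences.fasta --pssm-dir bundle/pssms \
              --labels bundle/labels.tsv --encoders gaac,dpc,psets,sgact \
              --out features.tsv
afpkit select --in features.tsv --step 0.25 --min-features 20 --seed 7 \
              --out-trace trace.json --out selected.tsv
afpkit cv --in selected.tsv --k 10 --model lxgb --seed 7
afpkit ablate --in features.tsv --ratios 1:1,1:3 --base 50 --k 5 --seed 7
```

Real PSI-BLAST ASCII profiles (one `<id>.pssm` per sequence) drop into the
same `--pssm-dir` slot.

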