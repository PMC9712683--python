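# Methods

## Problem and scope

afpkit classifies protein sequences as antifreeze proteins (AFPs) or
non-AFPs. The published benchmark this toolkit targets pairs 481 AFP
sequences with 9,193 non-AFPs drawn from Pfam families; profiles come from
PSI-BLAST searches against NCBI whose parameters (iterations, E-value,
database release) were never pinned, so numeric reproduction of the
published accuracy tables is out of reach without the authors' exact
profiles. The toolkit therefore implements the *method* completely —
encoders, selection, models, evaluation protocol — and validates it on a
synthetic benchmark whose ground truth is known by construction. Real
FASTA/PSSM inputs drop into the same interfaces.

## Encoders

**GAAC.** Frequencies of the five physicochemical groups G1=AGLIMV
(aliphatic), G2=DE (negative), G3=FWY (aromatic), G4=HRK (positive),
G5=CNPQST (uncharged); F(G_k) = n(G_k)/n. The groups partition the
20-letter alphabet, so the vector sums to 1.

**DPC.** Counts of the 400 ordered adjacent pairs divided by the number of
windows, L−1. The denominator is read as the number of dipeptides occurring
in the sequence rather than the constant 400: that is the standard
composition convention, makes the vector sum to 1, and keeps values
length-compositional.

**Profile normalization.** Raw PSI-BLAST log-odds are squashed elementwise
by the logistic sigmoid f(t) = 1/(1+e^(−t)). Only the first 20-column
log-odds block of the ASCII file is used; the percentage block is already
bounded and carries no extra information for these descriptors. The map is
monotone, so within-column score order is preserved. Double application is
refused programmatically because it silently compresses profiles toward
0.5.

**Three-way partition.** Rows split into blocks of ⌊L/3⌋, ⌊L/3⌋ and
L−2⌊L/3⌋; the remainder goes to the third block, consistent with the
floor operator in the partition definition. Internally the ranges are
half-open and 0-based; user-facing output is 1-based to match PSSM file
positions. L ≥ 3 is required to partition at all, and each block must be
strictly longer than the largest lag/rank applied to it, which the
encoders enforce with explicit errors (so the practical floor for default
settings is L ≥ 6, and the synthetic generator never emits sequences
shorter than 9).

**PseTS-PSSM.** Default: per-slice column means, 3 × 20 = 60 features,
matching the descriptor's stated dimensionality. The pseudo sequence-order
correlation factors (per column, mean squared difference between entries a
fixed rank apart) are implemented and exposed through
`EncoderConfig(pse_mode=..., pse_ranks=...)` but default *off*: the
source text defines them yet its printed feature count (60) excludes them,
and which variant produced the published model is not decidable from the
text. Both readings are therefore available; the default follows the
printed count.

**Sg-PSSM-ACT.** Per segment and lag, the per-column lagged autocovariance
using the segment's own column mean — the defining equations subscript the
mean by segment, so no global mean is ever used, and pairs never straddle
segment boundaries. The equations enumerate lag = 1, 2 (which would give
120 features) while the stated dimensionality is 60; as with PseTS-PSSM
the printed count wins by default (`act_lags=(1,)`) and the two-lag
variant is a configuration away. The third-segment normalizer is the
number of summed terms (segment length − lag), matching the first two
segments; the source's written denominator for that segment appears to be
a typo and would not equal the term count.

**Feature names** are a stable API of the form `ENC.detail`
(`DPC.AC`, `PSETS.slice3.mean.W`, `SGACT.seg2.lag1.K`) so selection traces
are auditable; a golden-file test freezes the default 525-name list.

## Feature selection (ERT-RFE)

Each round fits an extremely-randomized-trees ensemble on the surviving
features, records stratified k-fold accuracy of that subset, ranks
features by mean impurity decrease (the canonical ERT importance) and
removes the `step` lowest-ranked, breaking importance ties by dropping the
lexicographically later name first so runs are exactly reproducible. The
subset with maximal CV accuracy wins; ties prefer the smaller subset. The
inner scorer uses k = 5 folds, deliberately distinct from the outer
10-fold protocol, and 250 trees by default (both unstated in the source;
chosen as conventional values). `step` defaults to 1 and accepts a
fraction for wide matrices. A per-encoder pathway
(`select_per_encoder`) runs RFE within each encoder block and fuses the
winners, since the published 161-feature set is describable by either
pathway.

## Models and evaluation

LXGB is LightGBM's leaf-wise boosting with the published hyperparameters —
max depth 8, alpha (L1) 1, eta (learning rate) 0.1, lambda (L2) 1, 500
estimators — mapped onto the standard gradient-boosting parameter names.
RF and ERT tree counts are unstated in the source; 500 is used to parallel
the boosting count, seeded. Predictions are probability-like scores,
thresholded at 0.5; score alignment is by feature *name*, never column
position, and a name mismatch is an error.

Threshold metrics come from the confusion pooled across folds
(micro-average); per-fold reports and the macro-averaged accuracy are also
attached because the source does not say which it used. MCC uses the
standard full-numerator formula with a zero-marginal convention of 0.
AuROC is the trapezoid area of the threshold-swept ROC (tied scores
grouped, so constant scores give exactly 0.5) and AuPR the step-wise
interpolated area. k-fold assignment is stratified and seeded; k equal to
the dataset size degenerates to leave-one-out. The imbalance ablation
draws the stated positive:negative counts (1:1 = 300:300, 1:2 = 300:600,
1:3 = 300:900 by default) without replacement, seeded, and re-runs the CV
protocol per ratio.

## Synthetic benchmark

The generator emulates the two places a real AFP benchmark carries class
signal, independently:

- *Composition*: residues are drawn by sampling a physicochemical group
  from a per-class weight vector, then a residue uniformly within the
  group. The gap between class weight vectors is exactly the GAAC-level
  effect size.
- *Profile*: each row mixes a one-hot log-odds pattern for its own residue
  (+6 own column, −2 elsewhere, the magnitude of a confident PSI-BLAST
  log-odds) with Gaussian noise, scaled by `pssm_signal` ∈ [0, 1] and
  rounded to integers to match the ASCII dialect. At signal 0 the profile
  encoders are provably uninformative.

Presets: **strong** (positive G1 weight 0.55 vs 0.15, profile signal 0.9 —
the parameter-recovery setting), **moderate** (G1 0.32 vs 0.18, signal
0.5 — for experiments that must not saturate, such as the imbalance
direction test), **null** (identical uniform weights, signal 0). Default
lengths are uniform on [40, 100], typical of the short AFP sequences in
the benchmark, with a hard floor of 9 so every partition is valid at the
default lags. Rendered profile files round-trip bit-exactly through the
parser.

What the generator does *not* emulate: real AFP structural motifs, Pfam
family structure, homology between records, or realistic inter-column
covariance in profiles. Passing recovery tests therefore demonstrates the
pipeline's correctness and sensitivity under controlled signal, not
expected accuracy on biological data.

## Problem sizes used in the checks

The automated checks run the full pipeline at sizes chosen to make the
statistics stable while staying desk-scale: parameter recovery uses the
300+300 presets with fractional-step RFE (step 0.25 down to 30 features,
100-tree inner ensembles) before the default 500-tree LXGB tenfold CV; the
feature-recovery experiment uses 100 regenerations of a 100-record,
10-feature matrix with three features shifted by 3 SD; the imbalance
direction check uses 100 seeded repeats at 60:60 vs 60:180 with the
moderate preset and 100-tree LXGB under fivefold CV; oracle-equivalence
checks use 200 random profiles and 1,000 random confusion tables.

## Known limitations

- Real-profile reproduction of the published tables requires the authors'
  PSI-BLAST configuration, which is unpinned; the toolkit consumes PSSM
  files but cannot regenerate theirs.
- The negative-sampling policy behind the published balanced experiments
  is unstated; experiments here record their seeded draws in report
  metadata instead of guessing a canonical split.
- The published 161-feature optimal set cannot be re-derived without the
  real profiles; both selection pathways that could have produced it are
  provided.
- Sequences shorter than 3 (partition) or 3×(lag+1)-ish floors (encoders)
  are rejected rather than padded; real datasets contain few such
  sequences and padding would distort the autocovariance.
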