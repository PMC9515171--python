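# Methods

## Overview

`pathdrp` models drug response of cancer samples as a function of two
feature blocks: per-sample **pathway activity scores** computed from bulk
or pseudo-bulk RNA-seq, and a fixed-length **drug descriptor** derived
from the compound's SMILES string. Each training row is one
*(sample, drug)* pair; the target is the natural-log IC50 (regression) or
a binary responder label (classification). Because the drug is itself
featurized, one model covers all compounds and can score compounds absent
from training.

## Expression normalization

All scoring operates on log2(TPM + 1). Supported input units and their
conversions:

| unit | conversion |
|---|---|
| TPM | log transform only |
| RPKM / RSEM scaled estimate | rescale each column to sum to 1e6, then log |
| UMI counts | rescale to 1e6 (no length correction; UMI counts are length-free), then log |
| raw read counts | divide by gene length (bp), rescale to 1e6, then log; genes without a known length are dropped |

Duplicate gene identifiers (e.g. several Ensembl IDs per symbol) are
collapsed by arithmetic mean **on the linear scale** before the log
transform. The expressed-gene filter keeps a gene when its TPM is ≥ 1 in
at least ⌈0.10 · n⌉ samples (the ceiling is our choice where the rule's
boundary on fractional sample counts is ambiguous; it is the stricter
reading). Highly-variable-gene selection ranks genes by CV² =
var/mean² with the n−1 variance estimator, mean-zero genes last, ties in
input order.

## Pathway scoring

The per-sample enrichment statistic follows the GSVA construction for
log-scale expression:

1. **Kernel CDF.** For gene *i*, ẑᵢⱼ = (1/n) Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ) with
   hᵢ = sᵢ/4 (per-gene sample SD). Genes with sᵢ = 0 carry no ranking
   information and are dropped (logged).
2. **Symmetric rank statistic.** Genes are ranked per sample by
   decreasing ẑ (ties broken by input order — a documented determinism
   choice); r̃ᵢⱼ = |p/2 − rank|.
3. **Weighted KS walk.** For set γ, ν(ℓ) accumulates member mass
   (weights r̃^τ, τ = 1) minus non-member mass 1/(p − |γ|) down the
   ranking. Two score variants are exposed: `maxdev` (the extreme of
   larger magnitude) and `diff` (max(0, max ν) − max(0, −min ν), the
   default, matching the cited tool's default). When the two extremes
   tie in magnitude within 1e-12, `maxdev` resolves to the positive
   extreme; without a tolerance the choice would flip on
   summation-order rounding.

Sets are intersected with the measured genes and must retain ≥ 5 members
(`min_size=5`); a set spanning the entire universe is dropped because the
non-member term would divide by zero. Scores lie in [−1, 1], strictly
inside except for degenerate tiny instances where a set occupies one end
of the ranking exactly.

Missing pathway features at prediction time are kNN-imputed: the missing
entry becomes the mean, at that column, of the k = 10 nearest rows by
Euclidean distance over mutually observed columns; a row with no usable
neighbor falls back to its own observed mean (logged).

## Drug descriptors

A SMILES string is cut into overlapping character 8-mers (a string
shorter than 8 is its own token) and the descriptor is the mean of the
k-mer embedding vectors, length 100 by default. The original pre-trained
PubChem word embeddings are not redistributable, so the embedding source
is pluggable:

- **hashed** (default): each k-mer maps through a seeded BLAKE2 hash to a
  unit-variance Gaussian vector — deterministic from (seed, k, dim),
  corpus-free, and distinct k-mers are near-orthogonal at dim 100, so
  shared substructure strings produce correlated descriptors;
- **trained**: windowed k-mer co-occurrence → positive PMI → truncated
  SVD (the implicit factorization behind skip-gram vectors), fitted on a
  user corpus;
- **loaded**: a k-mer → vector TSV.

No SMILES canonicalization is applied by default.

## Dataset assembly and response cleaning

Duplicate LN IC50 measurements for a (sample, drug) pair are averaged;
conflicting binary labels are an error. IC50 outliers can be removed with
the Tukey IQR rule (retain Q1 − 1.5·IQR ≤ v ≤ Q3 + 1.5·IQR, type-7
quartiles — the interpolation convention is our choice). The assembled
table is F = P + E columns wide (pathway block then drug block); with the
1329-set canonical-pathway collection and 100-dim descriptors, F = 1429;
the tumor-classification configuration (1327 scorable sets) gives 1427.
Column order is serialized in a JSON schema so models are never applied
to permuted features. No feature scaling is applied by default: pathway
scores already live in (−1, 1) and hashed descriptors are unit-scale.
Heatmap-style z-scoring of predictions is per drug across samples (the
axis that compares samples within one drug's sensitivity range).

## Splitting

Random row-level splits leak expression profiles, so all splits operate
on sample groups (cell lines/patients): groups are shuffled with the seed
and assigned whole to the test side until the test row count first
reaches (1 − frac) of rows (row-targeted, because groups carry unequal
drug counts); the remaining groups are dealt round-robin into k = 5
validation folds. A leakage checker asserts no group reaches two
partitions and no row sits on both sides.

## Model

Regression network: input F → dense 512 (ReLU, fixed) → L ∈ [2, 6]
hidden layers of shared width W ∈ {128, 132, …, 256} (ReLU, dropout rate
∈ {0.1, …, 0.5} after every hidden layer) → linear output; Adam with
lr ∈ {1e-3, 1e-4, 1e-5}; MSE loss; mini-batches of 128; 30 epochs during
tuning and 50 for final models; no early stopping. The classifier
variant ends in a sigmoid with binary cross-entropy. The net, Adam and
inverted dropout are implemented in numpy (float32 internally — halves
the cost at no practical accuracy loss; predictions are returned as
float64) and are exactly reproducible from the seed on a fixed platform.

Interpretation choices where the architecture description is ambiguous:
L counts the tunable hidden layers *after* the fixed 512 layer; a single
width W is shared by all tunable layers; dropout uses one shared rate.

**Hyperparameter search** draws a budgeted candidate pool from the
grids and selects per cross-validation fold by validation loss. The
draw is stratified over the learning-rate grid (candidate *i* cycles the
lr grid, other dimensions uniform) because lr decides whether the net
trains at all: a small unstratified pool can consist entirely of
lr = 1e-5 configurations, which stay near-constant within the epoch
budget. Two strategies share this contract: plain random search (each
candidate trained for the full 30 tuning epochs) and the default
successive halving (all candidates for 10 epochs, the top half for the
full 30), which screens twice the configurations per unit compute — at
small budgets a full-epoch pool can still consist solely of
architectures that underperform the mean predictor. The default pool
size is 6. The per-fold winners are refit on the full training rows to
form a 5-member ensemble; member predictions are exposed individually
and the default aggregate is their mean.

**Baselines.** Random forest (per fold: grid over mtry 1..10 ×
trees 100..1000 step 100, min validation MSE) and elastic net (per fold:
25 bootstrap resamples scoring an (alpha, l1_ratio) grid by RMSE), each
refit on the full training rows, five models per protocol. The elastic
net grid (alpha ∈ {1e-3, 1e-2, 1e-1, 1}, l1_ratio ∈ {0.1, 0.5, 0.9}) is
a compact default. Tests exercise the baselines on reduced grids to keep
the suite fast; the defaults are the full grids.

## Metrics

Pooled regression reports Pearson ρ, R², MSE and RMSE over all aligned
(sample, drug) pairs, with **R² defined as ρ²** — the convention of the
metric tooling this field's sensitivity studies report with, and the one
consistent with published (ρ, R²) pairs such as (0.88, 0.77). Per-drug ρ
requires ≥ 3 pairs and nonzero variance on both sides; other drugs are
reported as undefined with a reason. Classification reports AUC
(rank-based, tie-corrected), AUC-PR (precision–recall step integration)
and F1 at threshold 0.5.

## Synthetic screen

The generator emulates a pharmacogenomic screen with known truth. Per
sample s and pathway k, an activity a_sk ~ N(0,1); member genes shift by
δ·a_sk (δ = 2.0 log2 units) over a per-gene baseline ~ U(2, 8) plus
N(0, 0.4) noise, clipped at 0 (δ = 5× gene noise keeps the signal
comfortably detectable by the scorer). Drugs fall into families sharing
a target-pathway set and SMILES motif substrings, so descriptors carry
target information and held-out drugs of a known family remain
predictable; responses follow

    y = μ + Σₖ w_dk · a_sk + ε,   ε ~ N(0, σ²)

with w = β on targets, 0 elsewhere; defaults β = 1.5, σ = 0.5, μ = 2.5
(a GDSC-like LN IC50 scale), 600 genes × 120 samples, 40 sets of 10
genes, 25 drugs with 3 targets each in 8 families. The linear generating
function was chosen deliberately: recovery is provable against a
closed-form truth rather than merely plausible; a nonlinearity can be
layered on by squashing. What the generator does **not** emulate:
realistic transcriptomic covariance, dose–response curve shape,
pharmacological IC50 scales, batch structure, chemically valid SMILES.
Passing recovery therefore demonstrates that the pipeline's plumbing and
learners recover a known pathway-by-drug signal under group-disjoint
splitting — not that the same accuracy transfers to real screens.

At these benchmark sizes (3,000 rows, 140 features, tuning pool 6 under
successive halving) one recovery run takes ≈ 90 s on one CPU core. Recovery is inherently
stochastic: the acceptance check asks pooled held-out ρ ≥ 0.6 in at
least 2 of 3 seeds, and an unlucky seed (hold-out groups plus candidate
draw) can land below the bar while a fixed sensible configuration clears
0.8 on the same data.

## Numerical details and edge cases

- Kernel evaluation is blocked over genes (256/block) to bound the p×n×n
  intermediate.
- Zero member mass in a walk (all member r̃ exactly 0 — only possible for
  a single mid-rank gene) falls back to uniform member weights, logged.
- A zero-variance drug column z-scores to all zeros (logged) rather than
  NaN.
- NaN/inf training loss aborts with the offending configuration named;
  there is no silent retry.
- Batch size is reduced to the row count for tables smaller than 128
  rows (logged).
- All randomness is keyed to explicit integer seeds; the pipeline
  expands one master seed per stage via `SeedSequence`.

## Known limitations

- Per-drug correlations on the synthetic screen are much weaker than the
  pooled correlation (few samples per drug in a 10% test split); the
  pooled number is the headline metric, as in the modeled studies.
- The hashed embedding encodes substructure identity, not chemistry:
  two drugs are similar only insofar as they share literal SMILES
  substrings.
- The trained embedding's SVD sign is fixed by the solver seed, not by
  any chemical convention.
- `maxdev`/`diff` agree when the walk stays single-signed and can
  otherwise differ in sign; the variant is recorded on every score
  matrix.
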