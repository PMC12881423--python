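# Methods

## Problem setting

Driver genes — the small subset of genes whose somatic mutations causally
promote tumor initiation and progression — are hard to separate from the
bulk of passenger-mutated genes. The package frames the task as
semi-supervised node classification on a gene–pathway hypergraph: genes are
nodes, each curated pathway is one hyperedge joining all of its member
genes, and a hypergraph convolutional network scores every gene's
probability of being a driver. Labeled drivers and curated non-drivers
supply the supervision; all remaining genes stay in the graph as unlabeled
nodes, contributing to message passing and forming the discovery pool.

## Hypergraph construction

Pathways arrive as GMT lines (name, description, member symbols). Pathway
names containing cancer terms (`cancer`, `tumor`, `tumour`, `carcinoma`,
`oncogen`, `melanoma`, `leukemia`, `glioma`; configurable) are removed
before construction so that topology itself cannot encode the labels.
Member sets are optionally intersected with a gene universe (e.g. genes
with omics measurements); hyperedges with fewer than `min_edge_size = 2`
surviving members are dropped, since singleton edges contribute only
self-loops. Gene identifiers are uppercase symbols matched exactly.
Whether pathway *descriptions* should also be screened is left to the
caller via the blacklist — only names are screened by default.

The propagation operator is

    P = D_v^(-1/2) H W B^(-1) H^T D_v^(-1/2)

assembled as `M Mᵀ` with `M = D_v^(-1/2) H (W B^(-1))^(1/2)`, which makes
symmetry exact by construction. Genes with zero pathway degree get zero
rows/columns (pseudo-inverse convention for `D_v^(-1/2)`); they are not
dropped, because the readout's skip connection to `X^(0)` still scores them
from their own features. Incidence and operator are scipy CSR matrices, so
matrix–vector products cost O(nnz).

**Hyperedge weights.** The published idea — weight a pathway by the number
of known drivers it contains — leaves the exact formula open; we use
`w_j = s + |e_j ∩ training positives|` with smoothing `s = 1`, so
driver-free pathways keep baseline propagation and the graph reduces to the
unweighted case when no labels are available. `s = 0` is allowed and
silences driver-free pathways entirely. Weights are recomputed inside every
cross-validation round from that round's training positives only; the test
suite asserts *exact* invariance of weights and test scores under
permutation of held-out labels.

## Node features

Three families, used alone or concatenated:

* **Incidence-based** (d = m): the gene's binary pathway-membership row —
  pure topology.
* **Core omics** (d = 3 per cancer type; 48 in the 16-type pan-cancer
  setting): per type,
  1. *mutation* — fraction of samples with ≥1 non-silent mutation in the
     gene, divided by gene length in kb. Samples with more than 1,000 total
     non-silent mutations (a conventional hypermutator cut-off; the
     reference protocol does not state one) are excluded first. A
     total-count-per-kb variant is exposed via `per_sample_total`.
  2. *expression* — `log2((mean tumor FPKM + c) / (mean normal FPKM + c))`
     with pseudocount `c = 1e-3`, below typical detection; a matched-pair
     mode (mean of per-pair log ratios) is available when a pairing map is
     supplied.
  3. *methylation* — mean tumor beta minus mean normal beta, on tables
     already aggregated probe→gene by the mean.
* **Comprehensive** (44 columns in the reference table): curated per-gene
  functional annotations loaded from delimited text; non-numeric columns
  are dropped with a warning, missing values are median-imputed per column.

Standardization is z-scoring with statistics fit on **training genes only**
(the `Standardizer` is returned for reuse on validation/test rows). Omics
values missing for a gene are imputed as 0 *after* standardization —
absence maps to the population mean — which keeps imputation leakage-safe.
Whether the reference protocol standardizes at all is unstated; both the
choice and its parameters are explicit and configurable here.

## Network and training

Defaults: 2 convolution layers, hidden width 128, ReLU, dropout 0.5 applied
to the input of every convolution layer during training (where dropout acts
is unstated in the reference description; this choice is configurable),
readout = concat(`X^(0)`, `X^(1)`, …, `X^(L)`) → trainable linear
projection to the hidden width, MLP head hidden → hidden/2 → 1 with a
logistic output. Loss is mean binary cross-entropy over labeled genes with
probabilities clipped to `[1e-7, 1-1e-7]`. Optimization is full-batch AdamW
(lr 1e-3, decoupled weight decay 5e-4 on weight matrices, not biases) for
at most 300 epochs with early stopping on validation loss (patience 30) and
restoration of the best-validation parameters.

The network, its analytic gradients and the optimizer are written directly
on numpy/scipy-sparse arrays. The backward pass exploits the operator's
symmetry (`Pᵀ = P`); where the probability clip is active the loss is
treated as locally flat. A central-difference gradient check on a 5-gene,
2-edge toy pins backward to forward at 1e-4 relative error; the comparison
uses an absolute floor of 1e-6 in the denominator because analytically-zero
gradients (ReLU-dead paths) would otherwise amplify finite-difference
roundoff into the ratio. Everything is driven by one seeded
`numpy.random.Generator` (initialization, then dropout masks), so a seeded
training run is bit-reproducible.

## Evaluation protocol

Stratified splits deal shuffled positives and negatives round-robin into k
folds, so per-fold class counts differ by at most one. The nested protocol
is 5 outer folds × 4 inner folds × 5 seeds. Per outer round: hyperedge
weights from outer-training positives; hyperparameter selection (when a
grid is given) by mean inner-fold validation AUPRC — AUPRC because it is
the lead metric under class imbalance; retraining on the full
outer-training set with the first inner fold as the early-stopping
validation split; scoring of the untouched test fold.

Metrics: AUROC delegates to scikit-learn's Mann–Whitney implementation
(ties count 1/2); AUPRC is the average-precision form (mean over positives
of precision at their ranks) implemented in-package because its tie-break —
stable sort on descending score — is part of the contract; F1 uses a 0.5
threshold (configurable) and returns 0 when nothing is predicted positive.
Ranked lists break ties by descending score then ascending gene id, so
reports are deterministic. Hits@K counts known positives in the top K;
Precision@K = Hits@K / K; K above the list length is clamped with a
warning. Classification metrics aggregate as mean ± population std over
folds × seeds. Ranking metrics are computed on the pooled held-out ranking:
per seed each labeled gene is scored exactly once while held out, scores
are averaged over seeds, and the curve is computed on that ranking.
Discovery output — ranking unlabeled genes — is a separate, metric-free
table produced by the `rank` pipeline stage.

By default `CVPlan.grid` is empty, which skips the inner search and trains
with the base configuration (the inner split still provides the validation
set); this keeps the default 25-training protocol at desk scale. Grid
search over the full inner 4-fold loop is implemented and exercised in the
test suite on a smaller problem.

## Synthetic benchmark

The generator emulates the study design, not the biology, at desk scale.
Defaults: 2,000 genes, 200 pathways with sizes uniform on 5–50, members
drawn uniformly without replacement (isolated genes allowed), 20 driver
pathways in which half the members are positives, an equal-sized negative
set drawn from genes in *no* driver pathway, 16 cancer types × 20
tumor/normal samples. Signal is planted in both topology (drivers co-occur
in pathways — the premise that makes pathway hypergraphs informative) and
features: the per-type mutation columns of positives are shifted by
`effect_size × noise_sd = 2` standard deviations. A single shifted column
alone yields AUROC ≈ Φ(2/√2) ≈ 0.921 (closed form for two unit-variance
Gaussians), which the test suite verifies; the full model sees 16 such
columns plus topology, so near-perfect recovery on the default benchmark is
expected, and observed.

Raw omics tables are generated alongside: Bernoulli mutation indicators
(35% vs 5% per-sample mutation probability), gamma-distributed FPKM with a
2-fold tumor shift, and clipped-normal betas with a +0.2 tumor shift for
positives. Exact numeric round-tripping from count/FPKM/beta tables to the
Gaussian feature matrix is not possible (the derived features have
different marginals), so the end-to-end contract is: generated tables pass
every feature-engineering precondition, and the derived
mutation/expression/methylation features separate positives from negatives
in the same direction — both asserted in tests. What passing on this
benchmark does **not** show: robustness to real mutational-signature
structure, batch effects, covariate-dependent missingness, or label noise
in curated catalogs.

## Pipeline

Stages `simulate → build-graph → featurize → labels → train → evaluate →
rank` each write artifacts plus a manifest (seed, config echo, SHA-256 of
inputs) under the output directory; re-running an unchanged stage is a
no-op unless forced, and a missing upstream artifact raises an error naming
the stage to run first. Configuration is a strict-schema YAML (unknown keys
rejected) overridable by CLI flags.

## Problem sizes and known limitations

Tests and the acceptance script use the default 2,000-gene benchmark for
the protocol-level checks and smaller instances (≤ 500 genes) for unit and
example runs — sizes at which a full 25-training protocol completes in
minutes on one CPU. Training is full-batch; graphs are assumed to fit in
memory (dense fallbacks are fine for n·m ≤ 10⁶). Per-type driver curation
thresholds (≥ 15 drivers per cancer type, inclusive) and the three-step
negative exclusion are implemented, but real catalog ingestion (CGC/NCG
exports, literature-mined lists) is the caller's responsibility: label
files are one symbol per line. The model shares all hyperparameters across
cancer types; no pathway-overlap deduplication is attempted, so heavily
overlapping collections will smooth cancer-type-specific signal — a known
property of pathway-shared supervision.
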