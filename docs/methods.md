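# Methods

## The prediction task

For a panel of conditions profiled by RNA-seq, expression is reduced to
per-gene z-scores: FPKM values are replicate-averaged per condition,
genes with mean expression < 0.05 or coefficient of variation < 0.3 are
removed, and each remaining gene's log expression is standardized across
conditions (natural log, pseudocount 1; population formula, ddof = 0).
The target `y[g, c]` is therefore *relative* regulation — how unusually
high or low gene *g* sits in condition *c* — not absolute abundance. The
log base is irrelevant after z-scoring; the pseudocount only guards
zeros. Both are configurable.

Conditions are represented by the TF rows of the same z-score matrix
(the TF list is an input; discovering TFs from protein domains is out of
scope). Genes are represented by the 1 kb of sequence upstream of the
annotated start codon (5'UTR included, the usual fungal promoter window),
reverse-complemented for minus-strand genes so every promoter reads
5'→3' toward the gene; genes with less than 1 kb of upstream sequence
are dropped and reported. Sequences are one-hot encoded over five
channels A, C, G, T, N; IUPAC ambiguity codes are downgraded to N with a
warning rather than rejected.

## Architecture

Promoter branch (valid convolutions, stride 1):

    conv(256 kernels, length 9) -> maxpool(19) -> ReLU -> dropout(0.398)
    -> batchnorm -> conv(64 kernels, length 13) -> maxpool(8) -> ReLU
    -> dropout -> batchnorm -> flatten

For a 1000-bp input the length chain is 992 → 52 → 40 → 5, giving a
320-dimensional flattened representation. Valid padding is used so every
first-layer activation corresponds to a full 9-bp window — a requirement
of the motif-extraction step. Pooling before the ReLU equals the usual
conv→ReLU→pool order because max-pooling and ReLU commute.

TF branch: dense(n_tfs → 1024) → ELU → dropout(0.189).

Head: the two representations are concatenated and passed through three
dense→ELU→dropout(0.0166)→batchnorm blocks and a final linear unit. The
hidden widths of the three head layers are not fixed by the reference
configuration; this package uses a geometric taper 512/256/64 (config
field `head_sizes`).

Training minimizes mean squared error with AdamW (lr 1.02e-4, weight
decay 1.64e-3, batch 256), runs at most 60 epochs, early-stops after 5
epochs without validation improvement, and keeps the checkpoint with the
best validation Pearson r (the validation metric is r, not loss). The
learning rate is constant; an optional linear-warmup flag exists but the
reference describes no schedule.

Variants:

* **3'UTR branch** — a second CNN branch with identical geometry reads
  1 kb of 3'UTR; its flat representation is concatenated alongside
  (concat width 320 + 320 + 1024).
* **Mean-TF ablation** — the TF vector is collapsed to its scalar mean
  before concatenation (width 320 + 1), destroying TF identity while
  keeping overall expression level; used to show individual TF levels
  matter.
* **Frozen-conv transfer** — convolutional weights copied from a source
  model and frozen (bit-identical after retraining); TF branch and head
  are re-initialized and retrained on the target data.

### NumPy implementation

The layers (1-D valid convolution via pre-computed window matrices,
non-overlapping max pooling with floor truncation, inverted dropout,
batch normalization with running statistics, ELU/ReLU, dense) and the
AdamW optimizer are implemented directly in NumPy (`funprose.nn`) with
hand-written backward passes, float32 throughout. Every backward pass is
verified against central finite differences in the test suite. Batch
normalization uses learnable affine parameters, momentum 0.1 and eps
1e-5; evaluation mode uses running statistics, and evaluation-mode
forwards are pure (no state mutates), which makes predictions
bit-reproducible.

## Split regimes

* **elements** — 10 % of gene×condition cells to validation, 20 % to
  test, uniformly at random without stratification.
* **conditions / genes** — the same fractions applied to whole
  conditions or whole genes, so the tested axis is never seen in
  training.
* **clustered conditions** — conditions are clustered by their z-score
  columns (agglomerative, average linkage, Euclidean distance) and test
  conditions are whole clusters, so no test condition resembles any
  training condition. Clusters are accepted into the test set only while
  they move the total toward the 20 % target, which keeps one oversized
  cluster from swallowing the axis. Validation conditions are also
  cluster-disjoint by default (`strict_val`), the stricter reading.

## Interpreting the model

**Motifs.** For kernel *x*, the feature map `F_x[i, p]` is the post-ReLU
activation at window position *p* of promoter *i*. The top 0.5 % of
strictly positive activations are selected (ties at the threshold break
lexicographically by promoter then position, making extraction
deterministic); each selected window contributes its one-hot 5×9 window
to a weighted count matrix `T` with the window's own activation as a
scalar weight, and column normalization gives the PSWM `M`. The
originally published formula for `T` is typographically ambiguous about
whether the weight is indexed at the window anchor or at each offset;
weighting each window by its own activation is the only reading in which
all weights come from the selected top set, and matches standard
kernel→PFM practice.
Positional profiles count where along the promoter the selected
activations fall, smoothed by a centered 15-bp moving average that
shrinks at the edges; kernels are ranked by mean profile value within
300 bp of the start codon. The N row is kept internally and dropped
(with column renormalization) at MEME export, whose alphabet is ACGT.

**Network.** Integrated Gradients with a zero baseline and 20 steps
(right-endpoint Riemann sum) attributes each test-set prediction to the
TF inputs, the promoter held fixed; on any model linear in the TF input
the result equals w⊙x exactly, and the completeness identity
Σ IG = f(x) − f(0) is verified at 2000 steps in the tests. Per-gene
aggregation uses the **mean of |IG|** across the gene's test samples:
TF inputs are z-scored (mean 0 across conditions), so signed
per-condition attributions of an approximately linear effect cancel in
expectation and would systematically underrate genuine regulators — on
the synthetic benchmark the absolute aggregate raises edge-ranking AUROC
from 0.79 to 0.91 on the identical trained model. The signed aggregate
remains available (`aggregate="signed"`). Edges are pairs whose |score|
exceeds mean + 3 sd of all |scores| (the threshold multiplier is a
parameter; smaller panels may warrant 2–2.5). The network is analyzed as
an unweighted undirected graph for Louvain modularity communities;
degree statistics report cumulative histograms and the edge fraction
covered by the top-10 out-degree hubs. TF↔kernel association tests use a
one-sided hypergeometric over-representation of kernel-activated genes
(max activation over the promoter > mean + 1 sd across genes) among a
TF's targets, for TFs with ≥ 20 targets, Benjamini–Hochberg corrected
with matches at q ≤ 0.2; community term enrichment uses the same
hypergeometric machinery against the score-table universe at α = 0.05.
The background population for these tests is the score-table gene
universe (the source analysis does not state its background).

## The synthetic benchmark

The generator produces what the preprocessing pipeline would emit, with
the regulatory truth known exactly:

* **PWMs** — `n_motifs` column-stochastic 4×9 matrices, one Dirichlet
  draw per column with concentration 0.2 (sharp, information-rich
  columns, like curated TF-binding motifs); motif *i* belongs to TF *i*.
* **Promoters** — i.i.d. background at GC 0.40 (fungal promoters are
  AT-rich); for each (gene, motif) pair, with probability 0.15 one
  instance sampled from the PWM is planted at a uniform-random
  non-overlapping position.
* **TF expression** — a rank-4 latent-factor process plus independent
  noise, z-scored per row: conditions get correlated, clusterable
  structure without collinear TF rows.
* **Expression** — `y[g, c] = Σ_t β[t, g]·tf[t, c] + ε`, ε ~ N(0, 0.5²),
  then per-gene z-scoring. β is nonzero exactly for planted (TF, gene)
  pairs, |β| ~ Uniform[1, 2] with random sign — so a TF moves a gene
  precisely when its motif is present, the interaction the model must
  discover from sequence.

Defaults (600 genes, 20 TFs, 40 conditions, 8 motifs) define the
standard benchmark; generation is bit-reproducible from one seed.
About 27 % of genes receive no motif and are unpredictable noise rows,
which caps the attainable pooled correlation near 0.7 — observed
withheld-elements performance of the reduced model is r ≈ 0.67.

What the generator does **not** emulate: read-count sampling noise and
library-size effects (it starts at the z-score level), nonlinear or
combinatorial regulation (AND/OR logic between TFs), motif syntax
(orientation, spacing, multiple instances per gene — exactly one
instance per planted pair, which keeps the occupancy→effect mapping
unambiguous for scoring), chromatin context, and indirect regulation
through hidden intermediates. Passing recovery tests therefore
demonstrates that the pipeline detects additive motif-gated effects; it
does not certify performance on real panels, where the headline numbers
require external datasets and GPU-scale training.

## Problem sizes and numerical choices

The shipped default configuration is the full-size reference
(256 kernels, TF hidden 1024). Benchmark runs and tests use
`ModelConfig.small()`: 32 first-layer kernels, 32 second-layer kernels,
TF hidden 128, head 128/64/32, dropout 0.05/0.1/0.02, constant lr 4e-3,
weight decay 1e-4, at most 12 epochs (patience 5). The learning rate is
larger than the full-size reference value because the parameter count is
two orders of magnitude smaller; it was chosen once from convergence
profiles on the benchmark. Training is seeded and deterministic on one
device; dropout draws come from a generator derived from the model seed.

Degenerate inputs: constant expression rows are rejected with a pointer
to the CV filter; all-zero attribution tables yield an empty network
with a warning; inactive kernels (no positive activation) are flagged
and excluded from PSWM extraction; degenerate residual groups are
excluded from bias summaries with a warning. Trinarization assigns
values exactly 1 sd from the mean to the central class. Nearest-
neighbour baseline ties resolve to the lowest training-condition index.

## Known limitations

* The genes-withheld regime is weak at this scale (r ≈ 0 on the
  benchmark): with 420 training genes and ~90 promoters per motif, the
  reduced CNN barely generalizes motif detection to unseen promoters.
  The regime ordering (elements ≥ conditions ≥ genes) still holds.
* Batch-norm running statistics are estimated on the training
  distribution; under strong condition shift (clustered splits) this
  costs accuracy.
* The MEME export drops the N channel; motifs dominated by N windows
  are not meaningful outside the model.
* Integrated Gradients attributes to TF *inputs* only; promoter
  attributions (which bases mattered) are not implemented — kernel
  PSWMs cover the sequence side.
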