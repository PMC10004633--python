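# Methods

## Problem

Graph classification assigns one categorical label to an entire graph — e.g.
mutagenicity of a compound whose atoms are nodes and bonds are edges, or
enzyme/non-enzyme for a protein structure graph. Message-passing graph
convolutions solve this by iteratively mixing each node's features with its
neighbours', but deep stacks *over-smooth*: after many rounds of averaging,
all node representations converge and the graph's discriminative structure is
erased, which is why most graph convolutional models stay at 2–4 layers.

This package implements a deep (default 32-layer) architecture, DGCNNII,
whose convolution is designed so depth helps rather than hurts, together with
a quantitative per-layer smoothness diagnostic (MAD) that makes the
over-smoothing behaviour measurable.

## The non-local message-passing layer

One layer maps node features `Z^(t)` (n x c) to

    Z^(t+1) = sigma( (alpha * A_att^(t) Z^(t) + beta * Z^(t-1) + gamma * X)
                     ((1 - delta_t) I + delta_t W^(t)) )

with `Z^(0) = Z^(1) = X` (the stage's input features). The pieces:

- **Attention adjacency** `A_att`: for each node i and each j in
  N(i) ∪ {i}, a logit `e_ij = LeakyReLU(a^T [Wg z_i || Wg z_j])` is
  softmax-normalised over the neighbourhood, giving a row-stochastic matrix
  supported on edges plus self-loops. Aggregation therefore weights
  neighbours by learned relevance instead of plain degree-averaging (the
  degree-averaging limit is recovered exactly when the scorer `a` is zero,
  which is used as an oracle in the tests).
- **Dense and residual terms**: `beta * Z^(t-1)` re-injects the previous
  layer's output and `gamma * X` the stage input, so every layer's output
  retains a fixed fraction of un-smoothed information;
  `alpha = 1 - beta - gamma`. Defaults `beta = gamma = 0.1`.
- **Identity-mapped transform**: the linear map is
  `(1 - delta_l) I + delta_l W` with `delta_l = ln(lambda/l + 1)`
  (natural log, `lambda = 0.5`, `l` the 1-based layer index within its
  stage). Deep layers are thus increasingly close to a pass-through, which
  keeps very deep stacks trainable. The identity term is only defined for
  width-preserving layers; width-changing layers (each stage's last) use the
  plain transform `Y W`.
- **Activation**: ReLU throughout, including the final single-channel sort
  layer. ReLU can zero negative sort keys, creating ties in the final
  channel; ties are harmless because the subsequent sort falls back on all
  earlier channels (see SortPooling below). A `tanh` activation is available
  per stage via `StageConfig.activation`.

Choices the published description leaves open, fixed here as configuration
defaults: LeakyReLU slope 0.2; attention embedding width equal to the input
width (square `Wg`); a node attends to itself (`include_self_attention=True`
— without it the aggregation would discard a node's own current features);
weights Glorot-uniform, biases zero, attention scorer `a` initialised to zero
(training starts from uniform attention; `a_init="glorot"` gives random
non-uniform attention, used by the untrained smoothness experiments).

## Architecture

One-hot node labels are linearly projected to 128 channels; stage 1 runs 16
layers (15 x 128 channels, a dataset-dependent final width — presets ship
32/64/128/32/128 for the MUTAG/PTC/NCI1/PROTEINS/D&D benchmarks); the
stage-1 output is concatenated with the raw one-hot features and linearly
bridged back to 128 channels; stage 2 runs another 16 layers ending in a
single channel. The per-layer outputs of stage 2 are concatenated column-wise
into a 15*128 + 1 = 1921-wide multi-scale feature vector per node
(`concat_scope="both_stages"` additionally includes stage-1 outputs; the
default follows the reading that the concatenation happens after the second
stage). The delta schedule restarts at `l = 1` in each stage, treating each
stage as an independent convolution block.

**SortPooling** orders nodes by the last column descending, breaking ties on
earlier columns right-to-left and finally on ascending original node index,
then truncates or zero-pads to `k` rows. The index tie-break is the one
permutation-sensitive corner, and only matters when two nodes have fully
identical 1921-channel rows — in which case swapping them leaves the pooled
matrix unchanged anyway. By default `k` is the largest value such that at
least 60% of training graphs have >= k nodes, floored at
`pool_size * conv2_kernel` (= 10) so the readout convolutions fit; an
explicit integer overrides the rule.

**Readout** flattens the k x 1921 matrix and applies a 1-D convolution whose
kernel and stride equal the per-node width (16 output channels — equivalent
to a dense map per pooled node), max-pooling of size 2, a second 1-D
convolution (kernel 5, 32 channels), a 128-unit dense ReLU layer, dropout
0.5, and a softmax classifier. A literal small-kernel first convolution
(`conv1_kernel`) is exposed for experimentation, but the default follows the
per-node reading: a kernel of 2 sliding over a 1921-channel node vector would
mix unrelated coordinates of the multiscale vector and has no consistent
interpretation.

## Training protocol

Batch size 1 (one graph per Adam step), cross-entropy loss, dropout only
after the dense readout layer, epoch-level shuffling. The published protocol
defers the learning rate to earlier work without printing a number; the
default here is 1e-4, and the scaled-down experiments in this repository use
1e-3 (small synthetic graphs tolerate, and benefit from, the larger step).
Evaluation reports exact accuracy (argmax, lowest class index on ties), mean
cross-entropy, and — for binary tasks with both classes present — the
rank-statistic AUC with half-credit for ties. Cross-validation is stratified
10-fold (9:1 split); the published protocol does not say whether its folds
were stratified, and stratification was chosen because it reduces variance on
small datasets; `stratified=False` disables it. All randomness (fold
assignment, init, shuffling, dropout) derives from one seed, so reruns
reproduce reports exactly.

The whole network, its backpropagation and the Adam optimiser are implemented
in NumPy with dense per-graph matrices; gradients are hand-derived and
verified against central finite differences in the test suite (at smooth
points — finite differences straddle ReLU kinks, so the checks randomise
biases away from zero). Dense n x n attention matrices are adequate for the
intended graph sizes (tens to a few hundred nodes); very large graphs
(thousands of nodes) would need a sparse implementation, which is out of
scope.

## MAD: the smoothness diagnostic

For a layer's representation matrix `H`, pairwise cosine distances
`D_ij = 1 - cos(H_i, H_j)` are masked by a 0/1 matrix that zeroes the
diagonal and all adjacent pairs (neighbours are expected to be similar, so
the statistic targets non-neighbouring pairs; an all-pairs mask is available
as `mask_mode="all_pairs"`). Each row is averaged over its strictly positive
entries, and those row means are averaged over rows having at least one
positive entry; an entirely non-positive matrix yields 0. Zero-norm rows
(possible under ReLU) get distance 0 and are thereby excluded by the
positive-value filter. Distances within 1e-12 of zero are snapped to exactly
zero so float residue from identical rows does not leak past that filter.
MAD lies in [0, 1] for nonnegative representations (ReLU towers) and [0, 2]
in general. Lower MAD = smoother (more collapsed) representations.

Per-dataset profiles average the per-graph MAD uniformly over graphs (the
aggregation behind published per-layer figures is unstated; size-weighted
averaging is available). Profiles can be computed for trained or untrained
models; the smoothness-contrast experiment below uses untrained seeded
models, so it demonstrates an architectural property at initialisation, not
a claim about trained representations.

## Synthetic data

`generate_er_density_dataset` emulates small labeled molecular-graph
benchmarks: class-balanced Erdős–Rényi graphs whose edge probability depends
on the class (density is a structure an attention/degree-driven aggregator
can detect without label signal), node counts uniform in a range, and node
labels drawn from a class-biased categorical (`label_class_correlation`
interpolates between pure noise and a deterministic label-class link,
default 0.5). A single seed drives per-graph substreams, so datasets are
reproducible and stable under insertion/removal of graphs. What it does not
emulate: real molecular valence constraints, motif structure, degree
heterogeneity, or label-structure coupling beyond density — so passing the
synthetic experiments shows the machinery learns a planted structural signal,
not that benchmark accuracies transfer.

## Experiment scales and expectations

The repository's experiments are sized for a single CPU:

- **Smoothness contrast**: 200 ER graphs (p = 0.1 vs 0.3, 15–25 nodes),
  untrained two-stage towers of 8 layers x 32 channels, 20 paired seeds.
  The full architecture's final-layer MAD is compared against the plain-GCN
  ablation (beta = gamma = 0, delta = 1, uniform attention). The
  architectural final layer is the single-channel sort layer, where ReLU
  makes cosine distance degenerate (nonnegative scalars are all cosine-1),
  so the contrast is read at the deepest multi-channel tap — the last hidden
  layer of stage 2. The full model is expected to keep MAD several-fold
  higher in >= 90% of seeds.
- **Learnability**: two-stage 4+4 layers x 32 channels, k = 10, on 200 ER
  graphs (p = 0.10 vs 0.35, 15–25 nodes), 9:1 split, 30 epochs, Adam 1e-3,
  averaged over 3 seeds; held-out accuracy >= 0.90 is expected (the planted
  density signal is strong — a bare density threshold already separates the
  classes).
- **Ablation harness**: the published configuration grid (first stage only;
  one single 32-layer stage; 16 + {2, 6, 10, 14, 16}) at reduced width
  (16 hidden channels) trains one epoch on 40 synthetic graphs each, as a
  structural end-to-end check.

Benchmark accuracies on the real TUDatasets (MUTAG etc.) require external
downloads and are intentionally not part of the test surface; the reader,
presets and CLI support them.

## Degenerate inputs and numerical notes

Single-node and edgeless graphs run end to end (a node always attends to
itself; SortPooling zero-pads to `k`). Attention softmax is computed with
row-max subtraction; rows without support (possible only with self-attention
disabled on isolated nodes) are defined as all-zero. Argmax ties in
evaluation resolve to the lowest class index, max-pool ties to the first
position, and the training loop aborts with a diagnostic naming the epoch and
graph if the loss becomes non-finite.
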