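# Methods

## Model

A Tree-3 network is the layer chain conv → max-pool → tree-sampling → FC.

**Grouped convolution.** Each of the C input channels is convolved with
its own K filters of size f×f (f = 5 by default); channels never mix, so
the weight tensor is (C·K, 1, f, f) with C groups — element-for-element
the C × K × f × f filter bank.  The filters are *shared* across the M
branches: activations are computed once and reused, while the logical
per-branch connectivity is preserved for path analysis and
gradient-instance accounting.  Convolution is valid cross-correlation
(output side = input side − f + 1).

**Pooling.** 2×2 non-overlapping max-pooling, applied to post-activation
values.  The selected within-window index is recorded in the activation
trace; ties are broken toward the first (lowest flat index) maximum,
which makes every run bit-reproducible.

**Tree sampling.** The pooled (C·K, s, s) stack is tiled into slabs of
`r` consecutive rows and all columns.  The published geometry names a
(2 × 2 × 7) rectangle for the 32×32 case; the reading implemented here is
*two consecutive rows of the 14×14 square, all 14 columns, summed over
the K depth filters* — the only reading consistent with both the
(3K × M × 14 × 14) tree weight tensor and the (3M × 7) output.  (A
literal 2×2×7 block tiling would produce 7×7 output positions per map and
contradict both.)  Each branch m, channel c and slab j owns a private
weight per (filter k, row, column) position:

    pre[m, c, j] = Σ_k Σ_{row ∈ slab j} Σ_col W[cK+k, m, row, col] · pooled[cK+k, row, col]

Tree units are ordered branch-major (`u = m·C·J + c·J + j`).

**Readout.** One fully connected (C·J·M → classes) layer, softmax +
cross-entropy.  The combined softmax/cross-entropy derivative at the
logits is exactly `probs − one_hot`, so the pruned gradient rule needs no
σ′ factor at the output layer; this is a deliberate modelling choice that
makes the single-route product form exact.

**Biases.** All layers are bias-free: the single-route gradient product
contains no bias terms, and adding them would change the structural-zero
bookkeeping.  (There is no hidden bias option; a bias-free chain is the
model.)

**Ten-head variant.** Ten single-output heads sharing one conv layer are
realized as a single tree network with 10·M branches and a block-diagonal
readout mask: output h sees only the tree units of branches
[h·M, (h+1)·M).  Masked entries are zeroed at initialization, in the
forward product and in every gradient, so the representation is exactly
equivalent to ten separate heads feeding one softmax.

**LeNet-5.** The multi-route reference: conv(6@5×5) → pool → conv(16@5×5)
→ pool → FC 400→120→84→classes, 32×32 inputs only.  The first
convolution mixes channels (depth-C filters, 5·5·3·6 = 450 weights),
which is the reading consistent with the 352,800 first-layer
gradient-instance count.  ReLU is used throughout its hidden layers; the
original architecture predates ReLU, but the choice is irrelevant to the
structural counts this package uses LeNet-5 for, and keeps one activation
convention across architectures.

## Backward engines

Two engines compute the same mini-batch mean gradient of the
cross-entropy:

* **reference** — ordinary vectorized chain rule.  Max-pooling routes the
  gradient only to the recorded selected unit.  Checked against central
  finite differences (ε = 1e−6, hybrid tolerance 1e−5·(1+|g|)) in the
  test suite.
* **pruned** — the single-route product rule.  Per sample it (1) takes
  the active tree units (σ′ ≠ 0), (2) forms the downstream factor
  g[u] = σ′_tree[u] · Σ_o W_fc[u,o]·err[o], (3) accumulates tree and
  readout gradients over active units only, and (4) for each *selected
  and active* conv unit multiplies the input patch by
  σ′_conv · Σ_m W_tree·g.  Applications on dead routes are skipped, never
  computed.  Engine equivalence (≤ 1e−9 relative) over random ReLU and
  Sigmoid networks is the package's core correctness property; observed
  disagreement is at rounding level (~1e−16).

The gradient sum over a weight's applications, branches and the output
units is a convention of this implementation (the route rule itself is a
per-application statement); it is validated by engine equivalence.

With Sigmoid no σ′ is ever exactly zero, so the only structural zeros
come from non-selected pooling units; magnitude thresholding (below) is
the pruning mechanism in that regime.

## Optimization

SGD with Nesterov momentum in the standard look-ahead form

    d = g + α·w ;  v ← μ·v + d ;  w ← w − η·(d + μ·v)

with L2 weight decay α added to the gradient before the momentum update.
Defaults η = 0.075, μ = 0.965, α = 5e−5, batch 100 are the full-scale
offline-learning settings; the bundled quickstart uses η = 0.05, μ = 0.9,
α = 0, batch 20, which suits the small synthetic task.  Learning-rate
schedules are piecewise tables (held at the last value beyond their
range) or multiplicative decay (factor 0.6 every 20 epochs for the
largest configuration); the named full-scale schedules ship in
`engine.SCHEDULES`.  α is schedulable the same way (the full-scale tree
runs drop it to 1e−5 after epoch 50).  Mini-batch gradients use *mean*
reduction — standard for a mean cross-entropy, and stated here as a
convention rather than a claim about the original experiments.

## Route counting

`count_paths_exact` is memoized DP on an explicit unit-level DAG
(`count(node) = Σ count(successors)`), cross-checked against brute-force
DFS enumeration on small random graphs.  `first_layer_route_counts`
evaluates the same recurrence with layered array operations so the
full-size geometries certify in milliseconds; the two are cross-checked
on LeNet-5 (interior pooled unit: 4,032,000; corner conv unit: 161,280).

Two conventions are kept deliberately.  The *closed form* reproduces the
published arithmetic verbatim — 16 filters × 25 applications ÷ 4 (pooling
window) = 100, × 120 × 84 = 1,008,000.  The *exact* convention treats each
pooled unit as a single-selection funnel node: all four window members
enter the same pooled node, so pooling does not divide distinct-path
counts and the interior total is 400 × 120 × 84 = 4,032,000.  Reports
always tag which convention produced a number; neither is silently
"corrected" to the other.

Certification runs on the per-branch logical DAG (each branch owns its
conv instance).  On the physical graph a shared filter weight would
trivially have M routes; the per-branch graph is the dendritic picture
the single-route claim is about, and the report states the convention.

## Sparsity profiling

Zero-gradient fractions are measured with batch-1 gradients, one sample
at a time — batch averaging would sum across samples and destroy
structural zeros.  "Zero" means *structural* zero: the route crosses an
inactive ReLU unit or a non-selected pooling unit.  For the tree and
readout layers instances coincide with weight entries and the zeros are
counted directly in the gradient tensors; for the conv layer an instance
is one (filter position, channel, filter, application position, branch)
term, and the count is taken from the activation trace (a selected,
active conv unit contributes f² live instances per branch whose tree unit
is active).  A loop-based per-instance recount of reference-engine
products is the test oracle.  Means and standard deviations are over the
profiled samples (10 by default, configurable).

Magnitude pruning is a separate explicit policy: an absolute threshold
(`|g| < t → 0`) or a target active fraction (keep top |g|, ties toward
lower flat index), applied jointly across layers.  Threshold 0 is
bit-identical to no pruning, verified through a full training run.
Active-update accounting multiplies a layer's gradient-instance count by
an active fraction: the K = 6, M = 16 tree has 5×5×3×6×28×28×16 =
5,644,800 convolutional instances, and a 0.6% active fraction leaves
33,869 ≈ 34,000 updates.

## Synthetic task

The generator emulates a small labelled natural-image problem: each class
is a fixed ±1 patch of 5×5 pixels — the scale the conv filters detect —
at a class-specific anchor ((5c mod rows, 7c mod cols), channel c mod C),
with amplitude 1.0, plus N(0, 0.3²) pixel noise, clipped to [−1, 1].
Labels are exactly balanced; train and test are disjoint draws of one
seeded stream.  Defaults: 16×16×1 images, 10 classes, 40 train / 20 test
per class.  What it does **not** emulate: spatial correlations, object
variability, pose/scale changes, or class overlap of natural images — so
passing the scaled-down learning check (K = 2, M = 4 reaching well above
3× chance in ≤ 30 epochs, ~1 s on one CPU) demonstrates that the
architecture, engines and optimizer are wired correctly, not that the
full-scale success rates are reproduced.  Full-scale CIFAR-10/MNIST
success rates and the trained-network zero-fraction levels
(~0.97/0.88/0.72 for conv/tree/FC) require the external datasets and
hundreds of epochs; they are external full-scale targets only, and the
file readers (IDX, CIFAR binary batches) exist so such runs use the same
code path.

## Numerical and degenerate-input choices

- float64 throughout; no accumulated-precision tricks are needed at the
  sizes involved.
- ReLU derivative at exactly 0 is 0 (the unit counts as inactive).
- Max-pool ties: first maximum (row-major within the window).
- Piecewise schedules beyond their declared range return the last value.
- Degenerate 1×1 chains (f = p = r = 1) are valid and used as analytic
  test fixtures (the scalar route product).
- All-zero gradients produce an explicitly flagged empty histogram;
  log-spaced histogram edges are clamped to the observed min/max so
  boundary values are never excluded by rounding.
- He-normal initialization: σ = √(2 / fan_in) with fan_in the in-degree
  of one output unit (per-group channels × f² for conv, K·r·columns for
  tree sampling, column in-degree for FC, mask-aware).  The √2 gain is
  used for both ReLU and Sigmoid configurations — "He normal" names the
  scheme, not an activation-conditional gain.

## Problem sizes used by the checks

Engine equivalence runs 50 random tree networks on 12×12 inputs
(C ≤ 2, K ≤ 2, M ≤ 3); certification covers (K, M) ∈ {1, 2, 6, 15} ×
{1, 4, 16} at the full 32×32 geometry via the layered DP; learning sanity
trains K = 2, M = 4 on 400 synthetic images for 30 epochs.  These sizes
were chosen so the whole suite runs in seconds while every code path —
grouped conv, pooling selection, slab tiling, masked readout, both
engines — is exercised at full fidelity.

## Known limitations

- The pruned engine's per-active-position Python loop is clear and
  faithful to "skip, never compute", but slower than the vectorized
  reference engine; large runs should train with the reference engine
  (they are numerically interchangeable) and use the pruned engine for
  profiling and verification.
- Only the four layer kinds (grouped conv, max-pool, tree sampling, FC)
  are supported; filter-cross extensions, 1×1 convolution stages and
  skip/recurrent connectivity are out of scope.
- `profile_zero_fraction` is defined for tree-family specs; LeNet-5
  per-instance profiling would require per-route bookkeeping the
  multi-route graph does not admit cheaply.
- Checkpoints are NumPy `.npz` archives; portability beyond NumPy is not
  a goal.
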