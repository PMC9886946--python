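# treebp — tree-architecture networks with single-route pruned backpropagation

`treebp` implements and analyzes a three-hidden-layer *tree* network
("Tree-3") in which every weight is connected to every output unit by
**exactly one route**, together with the pruned backpropagation rule that
this structure makes possible.  It is aimed at researchers in
biologically plausible learning and efficient training who want a fully
inspectable, NumPy-only reference implementation: the forward pass, an
ordinary chain-rule backward pass, the single-route pruned backward pass,
exact route enumeration in the connectivity DAG, and gradient-sparsity
profiling are all first-class, tested operations.

## The architecture and the pruned gradient rule

A Tree-3 network for C-channel images consists of M parallel,
dendrite-like branches:

1. **Convolution** — K filters of size 5×5 per input channel (grouped:
   channels do not mix), shared across all M branches, followed by ReLU
   (or Sigmoid) and 2×2 non-overlapping max-pooling.
2. **Tree sampling** — each pooled map is tiled into non-overlapping
   slabs of `r` consecutive rows (all columns); each branch has a private
   weight per position, summed over the K depth filters, giving
   `C·J` units per branch (J = pooled rows / r).
3. **Readout** — one fully connected layer from the `C·J·M` tree units to
   the output units, then softmax with cross-entropy.

For 32×32 RGB inputs with K = 6, M = 16, r = 2 this is the canonical
geometry: conv output `3K×28×28`, pooled `3K×14×14`, tree weights
`3K×M×14×14`, tree output `3M×7 = 336` units, readout `21M×10`.

Because pooling, slab tiling and the single readout are all funnels, the
connectivity graph from any first-layer unit to any output unit contains
exactly one directed path.  The gradient of a convolutional weight is
therefore a bare product along its route,

```
Δ(W_conv) = Input · σ'_conv · W_tree · σ'_tree · W_fc · (Output − Output_desired),
```

summed over output units and over the weight's applications and branches.
With ReLU the σ′ factors are 0/1 indicators, so the gradient is
`Input · W_tree · W_fc · error` on active routes and **exactly zero**
whenever the route crosses an inactive unit or a non-selected pooling
unit — the pruned engine skips those applications outright.  In contrast,
for the five-hidden-layer convolutional LeNet-5 (kept here as the
multi-route foil) the closed-form count gives
`16 × 25 / 4 = 100` routes per first-layer unit after pooling and
`100 × 120 × 84 = 1,008,000` in total; exact DAG enumeration, which does
not divide by the pooling window, gives 4,032,000.

## Worked example

Print the shape table of the canonical tree and certify the single-route
property:

```
$ treebp describe --arch tree3 -K 6 -M 16
Type           Weight size        Input size  Output size
Conv2d         3x6x5x5 groups=3   3x32x32     18x28x28
MaxPool2d      2x2                18x28x28    18x14x14
Tree Sampling  18x16x14x14        18x14x14    336
FC             336x10             336         10

total parameters: 60258

$ treebp count-paths --arch lenet5 --convention paper
{
  "architecture": "lenet5",
  "convention": "paper",
  "routes_before_pooling": 400,
  "routes_after_pooling": 100,
  "fc_widths": [120, 84],
  "total": 1008000
}
```

Train a small tree (K = 2, M = 4) on the bundled synthetic 10-class task
and profile its gradient sparsity:

```
$ treebp train --out runs/quickstart
{
  "final": {
    "epoch": 29, "lr": 0.05,
    "train_loss": 0.00047696398747109904,
    "train_accuracy": 1.0,
    "test_accuracy": 1.0,
    "test_loss": 0.006956485463224248
  },
  "zero_gradient_fractions": {
    "conv": 0.8764756944444445,
    "tree": 0.5059027777777777,
    "fc": 0.4750000000000001
  }
}
```

The synthetic task plants one 5×5 pattern per class in noise, so a
correctly wired tree should reach perfect test accuracy in a few epochs —
`test_accuracy` is the fraction of held-out images classified correctly.
The `zero_gradient_fractions` are the mean fractions of gradient
*instances* (per-application, per-branch gradient terms) that are exactly
zero for a presented input: even on this small trained ReLU tree, ~88% of
convolutional gradient instances are structurally dead, and the
convolutional layer dominates the whole-step count.  Training driven by
the `--engine pruned` backward produces metrics identical (to 1e-9) to the
reference chain rule.

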