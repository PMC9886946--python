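"""Gradient sparsity: zero-fraction profiling, threshold pruning, accounting.

In a ReLU tree network most gradient instances vanish *structurally*: a
route is dead as soon as it crosses an inactive ReLU unit or a
non-selected max-pooling unit, and the single-route property means one
dead unit kills the whole instance.  :func:`profile_zero_fraction`
measures the per-layer fraction of such zeros over a dataset with
single-input (batch-1) gradients — batch averaging would destroy the
structural zeros, so profiling never batches.

Magnitude pruning (:func:`apply_threshold_pruning`) is a separate,
explicit policy: it zeroes stored gradient entries whose magnitude falls
below a threshold (or keeps only a target top fraction), which is how the
"only a fraction of a percent of gradient instances actually needs
updating" accounting (:func:`active_update_count`) is realized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architectures import (
    ArchitectureSpec,
    ConfigurationError,
    ConvLayer,
    FCLayer,
    PoolLayer,
    TreeSamplingLayer,
    count_gradient_instances,
)
from .engine import (
    GradientSet,
    backward_pruned,
    backward_reference,
    forward,
)

__all__ = [
    "SparsityProfile",
    "PruningPolicy",
    "MagnitudeHistogram",
    "profile_zero_fraction",
    "apply_threshold_pruning",
    "active_update_count",
    "gradient_magnitude_histogram",
]


# --------------------------------------------------------------------------- #
# zero-fraction profiling
# --------------------------------------------------------------------------- #


@dataclass
class SparsityProfile:
    """Per-layer zero-gradient fractions over a set of evaluated samples.

    ``layer_mean`` / ``layer_std`` map layer names (``conv``, ``tree``,
    ``fc``) to the mean and standard deviation over samples of the
    fraction of gradient instances that are exactly zero.
    ``whole_step_mean`` is the instance-weighted mean over layers, which
    the convolutional layer dominates whenever its instances dominate.
    """

    layer_mean: dict[str, float]
    layer_std: dict[str, float]
    instance_counts: dict[str, int]
    n_samples: int
    whole_step_mean: float
    whole_step_std: float
    per_sample: dict[str, np.ndarray]


def _tree_layers(spec: ArchitectureSpec):
    if spec.family not in ("tree3", "ten_tree3"):
        raise ConfigurationError(
            "sparsity profiling is defined for tree-family architectures")
    conv: ConvLayer = spec.layers[0]
    pool: PoolLayer = spec.layers[1]
    tree: TreeSamplingLayer = spec.layers[2]
    fc: FCLayer = spec.layers[3]
    return conv, pool, tree, fc


def profile_zero_fraction(spec: ArchitectureSpec, params, images: np.ndarray,
                          labels: np.ndarray | None = None,
                          engine: str = "pruned") -> SparsityProfile:
    """Fraction of zero gradient instances per layer, sample by sample.

    Each image is profiled with a batch-1 gradient.  Tree and readout
    instances coincide with weight entries, so their zeros are counted
    directly in the gradient tensors of the chosen ``engine`` (``pruned``
    or ``reference`` — they agree).  Convolutional instances are
    per-application-and-branch; an instance is zero exactly when its
    single route is blocked, so the count is taken from the activation
    trace: a selected, active conv unit contributes ``f**2`` live
    instances per branch whose tree unit on the route is active.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    if images.shape[0] == 0:
        raise ConfigurationError("empty dataset")
    conv, pool, tree, fc = _tree_layers(spec)
    backward = {"pruned": backward_pruned, "reference": backward_reference}[engine]
    c, k, m = tree.channels, tree.depth, tree.branches
    j, r = tree.slabs, tree.slab_rows
    f, p = conv.kernel, pool.size
    n_conv = count_gradient_instances(spec, 0)
    n_tree = count_gradient_instances(spec, 2)
    n_fc = count_gradient_instances(spec, 3)
    fracs = {"conv": [], "tree": [], "fc": []}
    from .engine import _selected_mask  # shared selection bookkeeping

    for b in range(images.shape[0]):
        trace = forward(spec, params, images[b])
        if labels is not None:
            target = np.asarray([int(labels[b])])
        else:
            # surrogate target when labels are absent: route activity does not
            # depend on the error vector, and the argmax class gives a
            # generically nonzero error for the tree/fc zero counts.
            target = np.asarray([int(trace.probs[0].argmax())])
        grads = backward(spec, params, trace, target)
        zc = grads.zero_counts()
        if fc.mask is not None:
            # masked entries are not instances
            fracs["fc"].append((zc[3] - int((fc.mask == 0).sum())) / n_fc)
        else:
            fracs["fc"].append(zc[3] / n_fc)
        fracs["tree"].append(zc[2] / n_tree)
        # conv: instance is live iff its conv unit is selected and active and
        # the branch's tree unit on the route is active
        sp_tree = trace.activation_derivative(2)[0].reshape(m, c, j)
        branch_live = (sp_tree != 0.0).sum(axis=0)             # (C, J) live branches
        sp_conv = trace.activation_derivative(0)[0]            # (C*K, H', W')
        argmax = trace.pool_argmax[1][0]
        live = 0
        for ci in range(c):
            # live branch count per conv row (slab of the pooled row)
            per_row = np.repeat(branch_live[ci], r * p)        # conv rows
            for ki in range(k):
                ch = ci * k + ki
                sel = _selected_mask(argmax[ch], p, sp_conv.shape[1:])
                active = sel & (sp_conv[ch] != 0.0)
                live += int((active.sum(axis=1) * per_row).sum())
        fracs["conv"].append(1.0 - live * f * f * (conv.in_channels // conv.groups)
                             / n_conv)
    counts = {"conv": n_conv, "tree": n_tree, "fc": n_fc}
    arr = {name: np.asarray(v) for name, v in fracs.items()}
    total = sum(counts.values())
    whole = sum(arr[name] * counts[name] for name in arr) / total
    return SparsityProfile(
        layer_mean={name: float(a.mean()) for name, a in arr.items()},
        layer_std={name: float(a.std(ddof=0)) for name, a in arr.items()},
        instance_counts=counts,
        n_samples=images.shape[0],
        whole_step_mean=float(whole.mean()),
        whole_step_std=float(whole.std(ddof=0)),
        per_sample=arr,
    )


# --------------------------------------------------------------------------- #
# magnitude pruning
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class PruningPolicy:
    """Magnitude pruning policy: absolute threshold or target top fraction.

    Exactly one of ``threshold`` (zero entries with ``|g| < threshold``)
    or ``target_active_fraction`` (keep the top fraction by ``|g|``,
    ties broken toward lower flat index) is given.
    """

    threshold: float | None = None
    target_active_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.target_active_fraction is None):
            raise ConfigurationError(
                "give exactly one of threshold / target_active_fraction")
        if self.threshold is not None and self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.target_active_fraction is not None and not (
                0 < self.target_active_fraction <= 1):
            raise ConfigurationError("target active fraction must be in (0, 1]")


def apply_threshold_pruning(gradients: GradientSet,
                            policy: PruningPolicy) -> tuple[GradientSet, float]:
    """Zero small-magnitude gradient entries across all layers jointly.

    Returns the pruned copy and the realized active (nonzero) fraction.
    A zero threshold leaves the gradients bit-identical.
    """
    pruned = gradients.copy()
    flat = np.concatenate([np.abs(g).ravel() for g in pruned.grads.values()])
    total = flat.size
    if policy.threshold is not None:
        thr = policy.threshold
        if thr > 0:
            for g in pruned.grads.values():
                g[np.abs(g) < thr] = 0.0
    else:
        keep = int(np.ceil(policy.target_active_fraction * total))
        order = np.lexsort((np.arange(total), -flat))          # |g| desc, index asc
        kept = np.zeros(total, dtype=bool)
        kept[order[:keep]] = True
        pos = 0
        for g in pruned.grads.values():
            n = g.size
            g.ravel()[~kept[pos:pos + n]] = 0.0
            pos += n
    active = sum(int(np.sum(g != 0.0)) for g in pruned.grads.values())
    return pruned, active / total


def active_update_count(spec: ArchitectureSpec, active_fraction: float,
                        layer_index: int = 0) -> tuple[int, int]:
    """Gradient instances of a layer times an active fraction.

    Defaults to the convolutional layer, which dominates the instance
    count.  Returns ``(nearest integer, nearest thousand)``; e.g. the
    K=6, M=16 tree at 0.6% active gives (33869, 34000) out of 5,644,800.
    """
    if not 0 < active_fraction <= 1:
        raise ConfigurationError("active fraction must be in (0, 1]")
    n = count_gradient_instances(spec, layer_index)
    exact = int(round(n * active_fraction))
    return exact, int(round(exact / 1000.0)) * 1000


# --------------------------------------------------------------------------- #
# magnitude histograms
# --------------------------------------------------------------------------- #


@dataclass
class MagnitudeHistogram:
    """Log-spaced histogram of nonzero gradient magnitudes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_nonzero: int
    empty: bool
    relative: bool = False


def gradient_magnitude_histogram(gradients: GradientSet, bins: int = 50,
                                 params=None,
                                 relative: bool = False) -> MagnitudeHistogram:
    """Histogram of ``|g|`` over nonzero entries, log-spaced bins.

    With ``relative=True`` (requires ``params``) the relative weight
    change ``|g / w|`` is binned instead, over entries where both the
    gradient and the weight are nonzero.
    """
    values = []
    for i, g in gradients.grads.items():
        a = np.abs(g).ravel()
        if relative:
            if params is None:
                raise ConfigurationError("relative histogram requires params")
            w = np.abs(params.weights[i]).ravel()
            ok = (a > 0) & (w > 0)
            values.append(a[ok] / w[ok])
        else:
            values.append(a[a > 0])
    v = np.concatenate(values) if values else np.array([])
    if v.size == 0:
        return MagnitudeHistogram(
            bin_edges=np.array([]), counts=np.array([], dtype=np.int64),
            n_nonzero=0, empty=True, relative=relative)
    lo, hi = v.min(), v.max()
    if lo == hi:                          # one magnitude: a single occupied bin
        edges = np.array([lo * 0.5, hi * 2.0])
    else:
        edges = np.logspace(np.log10(lo), np.log10(hi), bins + 1)
        edges[0], edges[-1] = lo, hi      # guard against rounding exclusion
    counts, edges = np.histogram(v, bins=edges)
    return MagnitudeHistogram(bin_edges=edges, counts=counts,
                              n_nonzero=int(v.size), empty=False,
                              relative=relative)
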