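"""Forward pass, reference and pruned backward passes, loss and optimization.

Two backward engines compute the same cross-entropy gradients:

``backward_reference``
    Ordinary full chain rule through every layer, vectorized.  Serves as
    the in-package oracle for the pruned engine (and is itself checked
    against central finite differences in the test suite).

``backward_pruned``
    The single-route rule for tree architectures.  Every weight reaches
    every output unit through exactly one route, so its gradient is the
    product along that route

        d(W_conv) = input * sigma'_conv * W_tree * sigma'_tree * W_fc
                    * (output - output_desired)

    summed over the output units and over the weight's applications and
    branches.  With ReLU the sigma' factors are active/inactive indicators
    and the product collapses to ``input * W_tree * W_fc * error`` on
    active routes and exactly zero otherwise.  Applications whose route
    crosses an inactive ReLU unit or a non-selected pooling unit are
    skipped outright, never computed.

The output layer is softmax + cross-entropy, whose combined derivative is
exactly ``output - output_desired``; no extra sigma' factor appears at the
readout.  Mini-batch gradients use mean reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architectures import (
    ArchitectureSpec,
    ConfigurationError,
    ConvLayer,
    FCLayer,
    NetworkParams,
    PoolLayer,
    TreeSamplingLayer,
)

__all__ = [
    "ActivationTrace",
    "GradientSet",
    "TrainingConfig",
    "LossReport",
    "SingleRouteError",
    "StaleTraceError",
    "forward",
    "backward_reference",
    "backward_pruned",
    "loss_cross_entropy",
    "sgd_step",
    "lr_schedule",
    "weight_decay_at",
    "train",
    "evaluate",
    "SCHEDULES",
]


class StaleTraceError(RuntimeError):
    """Backward called with a trace recorded under different parameters."""


class SingleRouteError(ValueError):
    """Pruned backward called on an architecture that is not single-route."""


# --------------------------------------------------------------------------- #
# activations
# --------------------------------------------------------------------------- #


def _act(kind: str, x: np.ndarray) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "linear":
        return x
    raise ConfigurationError(f"unknown activation {kind!r}")


def _act_deriv(kind: str, pre: np.ndarray) -> np.ndarray:
    # ReLU derivative at exactly 0 is taken as 0 (inactive), consistent with
    # the structural-zero bookkeeping.
    if kind == "relu":
        return (pre > 0.0).astype(pre.dtype)
    if kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-pre))
        return s * (1.0 - s)
    if kind == "linear":
        return np.ones_like(pre)
    raise ConfigurationError(f"unknown activation {kind!r}")


# --------------------------------------------------------------------------- #
# traces / gradients
# --------------------------------------------------------------------------- #


@dataclass
class ActivationTrace:
    """Everything one forward pass recorded.

    ``pre[i]`` / ``post[i]`` are the pre- and post-activation arrays of
    layer i (batch leading).  ``pool_argmax[i]`` holds, for pooling layers,
    the flat within-window index of the selected unit (first maximum on
    ties).  ``inputs[i]`` is the array fed to layer i.  ``probs`` is the
    softmax of the final output vector.
    """

    spec: ArchitectureSpec
    inputs: list[np.ndarray]
    pre: list[np.ndarray]
    post: list[np.ndarray]
    pool_argmax: dict[int, np.ndarray]
    logits: np.ndarray
    probs: np.ndarray
    params_token: tuple

    @property
    def batch_size(self) -> int:
        return self.inputs[0].shape[0]

    def activation_derivative(self, layer_index: int) -> np.ndarray:
        """sigma' of layer ``layer_index`` evaluated at the traced pre-activations."""
        layer = self.spec.layers[layer_index]
        kind = getattr(layer, "activation", "linear")
        return _act_deriv(kind, self.pre[layer_index])


@dataclass
class GradientSet:
    """Per-layer gradient tensors mirroring :class:`NetworkParams` shapes."""

    grads: dict[int, np.ndarray]

    def zero_counts(self) -> dict[int, int]:
        """Exactly-zero entries per weight tensor."""
        return {i: int(np.sum(g == 0.0)) for i, g in self.grads.items()}

    def nonzero_counts(self) -> dict[int, int]:
        return {i: int(np.sum(g != 0.0)) for i, g in self.grads.items()}

    def copy(self) -> "GradientSet":
        return GradientSet({i: g.copy() for i, g in self.grads.items()})


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _effective_fc_weight(layer: FCLayer, w: np.ndarray) -> np.ndarray:
    return w * layer.mask if layer.mask is not None else w


# --------------------------------------------------------------------------- #
# forward
# --------------------------------------------------------------------------- #


def _conv_forward(layer: ConvLayer, w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Grouped valid cross-correlation.  x: (B, Cin, H, W) -> (B, Cout, H', W')."""
    g = layer.groups
    cin_g = layer.in_channels // g
    cout_g = layer.out_channels // g
    win = sliding_window_view(x, (layer.kernel, layer.kernel), axis=(2, 3))
    # win: (B, Cin, H', W', k, k)
    outs = []
    for gi in range(g):
        wg = w[gi * cout_g:(gi + 1) * cout_g]                  # (cout_g, cin_g, k, k)
        xg = win[:, gi * cin_g:(gi + 1) * cin_g]               # (B, cin_g, H', W', k, k)
        outs.append(np.einsum("bcijuv,ocuv->boij", xg, wg, optimize=True))
    return np.concatenate(outs, axis=1)


def _pool_forward(layer: PoolLayer, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-pool; returns (pooled, argmax) with argmax the flat in-window index."""
    b, c, h, w = x.shape
    p = layer.size
    win = x.reshape(b, c, h // p, p, w // p, p).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(b, c, h // p, w // p, p * p)
    idx = win.argmax(axis=-1)                                  # first max on ties
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def _tree_forward(layer: TreeSamplingLayer, w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """x: (B, C*K, s_h, s_w) -> (B, M*C*J) branch-major."""
    b = x.shape[0]
    c, k, m = layer.channels, layer.depth, layer.branches
    j, r = layer.slabs, layer.slab_rows
    xs = x.reshape(b, c, k, j, r, layer.in_w)
    ws = w.reshape(c, k, m, j, r, layer.in_w)
    pre = np.einsum("bckjrv,ckmjrv->bmcj", xs, ws, optimize=True)
    return pre.reshape(b, m * c * j)


def forward(spec: ArchitectureSpec, params: NetworkParams,
            batch: np.ndarray) -> ActivationTrace:
    """Run one forward pass and record a complete :class:`ActivationTrace`.

    ``batch`` is (B, C, H, W); a single image (C, H, W) is promoted to a
    batch of one.  Activation precedes pooling (pooling selects among
    post-activation values).
    """
    x = np.asarray(batch, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != spec.input_shape:
        raise ConfigurationError(
            f"batch shape {x.shape[1:]} != spec input {spec.input_shape}")
    inputs: list[np.ndarray] = []
    pres: list[np.ndarray] = []
    posts: list[np.ndarray] = []
    pool_argmax: dict[int, np.ndarray] = {}
    for i, layer in enumerate(spec.layers):
        inputs.append(x)
        if isinstance(layer, ConvLayer):
            pre = _conv_forward(layer, params.weights[i], x)
            post = _act(layer.activation, pre)
        elif isinstance(layer, PoolLayer):
            pre, idx = _pool_forward(layer, x)
            pool_argmax[i] = idx
            post = pre
        elif isinstance(layer, TreeSamplingLayer):
            pre = _tree_forward(layer, params.weights[i], x)
            post = _act(layer.activation, pre)
        elif isinstance(layer, FCLayer):
            flat = x.reshape(x.shape[0], -1)
            pre = flat @ _effective_fc_weight(layer, params.weights[i])
            post = _act(layer.activation, pre)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown layer {type(layer).__name__}")
        pres.append(pre)
        posts.append(post)
        x = post
    logits = x
    return ActivationTrace(
        spec=spec, inputs=inputs, pre=pres, post=posts,
        pool_argmax=pool_argmax, logits=logits, probs=_softmax(logits),
        params_token=params.fingerprint(),
    )


# --------------------------------------------------------------------------- #
# loss
# --------------------------------------------------------------------------- #


@dataclass
class LossReport:
    """Mean cross-entropy and the per-sample output-error vectors."""

    value: float
    error: np.ndarray  # (B, classes): probs - one_hot(targets)


def _one_hot(targets: np.ndarray, classes: int) -> np.ndarray:
    t = np.asarray(targets, dtype=np.int64)
    if t.min() < 0 or t.max() >= classes:
        raise ConfigurationError(
            f"target index out of range [0, {classes}): {t.min()}..{t.max()}")
    out = np.zeros((t.shape[0], classes))
    out[np.arange(t.shape[0]), t] = 1.0
    return out


def loss_cross_entropy(trace: ActivationTrace, targets: np.ndarray) -> LossReport:
    """Mean cross-entropy of the traced softmax against integer targets.

    The exposed error vector ``probs - one_hot`` is the exact gradient of
    the loss with respect to the logits (times the batch size), i.e. the
    ``output - output_desired`` term of the pruned gradient rule.
    """
    classes = trace.probs.shape[1]
    onehot = _one_hot(targets, classes)
    z = trace.logits - trace.logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    value = float(-(onehot * logp).sum(axis=1).mean())
    return LossReport(value=value, error=trace.probs - onehot)


# --------------------------------------------------------------------------- #
# reference backward (full chain rule)
# --------------------------------------------------------------------------- #


def _conv_backward(layer: ConvLayer, w: np.ndarray, x: np.ndarray,
                   d_pre: np.ndarray, need_dx: bool) -> tuple[np.ndarray, np.ndarray | None]:
    g = layer.groups
    cin_g = layer.in_channels // g
    cout_g = layer.out_channels // g
    k = layer.kernel
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    dw = np.empty(layer.weight_shape)
    dx = np.zeros_like(x) if need_dx else None
    for gi in range(g):
        dg = d_pre[:, gi * cout_g:(gi + 1) * cout_g]           # (B, cout_g, H', W')
        xg = win[:, gi * cin_g:(gi + 1) * cin_g]               # (B, cin_g, H', W', k, k)
        dw[gi * cout_g:(gi + 1) * cout_g] = np.einsum(
            "boij,bcijuv->ocuv", dg, xg, optimize=True)
        if need_dx:
            # full correlation: pad d_pre and correlate with the flipped kernel
            wg = w[gi * cout_g:(gi + 1) * cout_g]
            dp = np.pad(dg, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
            dwin = sliding_window_view(dp, (k, k), axis=(2, 3))
            wf = wg[:, :, ::-1, ::-1]
            dx[:, gi * cin_g:(gi + 1) * cin_g] = np.einsum(
                "boijuv,ocuv->bcij", dwin, wf, optimize=True)
    return dw, dx


def _pool_backward(layer: PoolLayer, x_shape: tuple[int, ...],
                   idx: np.ndarray, d_out: np.ndarray) -> np.ndarray:
    b, c, h, w = x_shape
    p = layer.size
    dwin = np.zeros((b, c, h // p, w // p, p * p))
    np.put_along_axis(dwin, idx[..., None], d_out[..., None], axis=-1)
    return (dwin.reshape(b, c, h // p, w // p, p, p)
                .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w))


def _tree_backward(layer: TreeSamplingLayer, w: np.ndarray, x: np.ndarray,
                   d_pre_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = x.shape[0]
    c, k, m = layer.channels, layer.depth, layer.branches
    j, r = layer.slabs, layer.slab_rows
    d3 = d_pre_flat.reshape(b, m, c, j)
    xs = x.reshape(b, c, k, j, r, layer.in_w)
    ws = w.reshape(c, k, m, j, r, layer.in_w)
    dw = np.einsum("bmcj,bckjrv->ckmjrv", d3, xs, optimize=True)
    dx = np.einsum("bmcj,ckmjrv->bckjrv", d3, ws, optimize=True)
    return (dw.reshape(layer.weight_shape),
            dx.reshape(b, c * k, layer.in_h, layer.in_w))


def _check_trace(params: NetworkParams, trace: ActivationTrace) -> None:
    if trace.params_token != params.fingerprint():
        raise StaleTraceError(
            "activation trace was recorded under different parameters; "
            "rerun forward() before backward")


def backward_reference(spec: ArchitectureSpec, params: NetworkParams,
                       trace: ActivationTrace, targets: np.ndarray) -> GradientSet:
    """Exact cross-entropy gradients by the ordinary chain rule (mean reduction).

    Max-pooling routes the gradient only to the selected unit of each
    window.  Masked readout entries receive exactly zero gradient.
    """
    _check_trace(params, trace)
    b = trace.batch_size
    report = loss_cross_entropy(trace, targets)
    d = report.error / b                                       # d loss / d logits
    grads: dict[int, np.ndarray] = {}
    for i in range(len(spec.layers) - 1, -1, -1):
        layer = spec.layers[i]
        x = trace.inputs[i]
        if isinstance(layer, FCLayer):
            if i != len(spec.layers) - 1:
                # hidden FC: d arrives w.r.t. post-activation
                d = d * _act_deriv(layer.activation, trace.pre[i])
            # last layer: softmax + cross-entropy already folded into d
            flat = x.reshape(b, -1)
            dw = flat.T @ d
            if layer.mask is not None:
                dw = dw * layer.mask
            grads[i] = dw
            d = (d @ _effective_fc_weight(layer, params.weights[i]).T).reshape(x.shape)
        elif isinstance(layer, TreeSamplingLayer):
            d = d * _act_deriv(layer.activation, trace.pre[i])
            grads[i], d = _tree_backward(layer, params.weights[i], x, d)
        elif isinstance(layer, PoolLayer):
            d = _pool_backward(layer, x.shape, trace.pool_argmax[i], d)
        elif isinstance(layer, ConvLayer):
            d = d * _act_deriv(layer.activation, trace.pre[i])
            grads[i], dx = _conv_backward(layer, params.weights[i], x, d, need_dx=i > 0)
            d = dx if dx is not None else d
    return GradientSet(grads)


# --------------------------------------------------------------------------- #
# pruned single-route backward
# --------------------------------------------------------------------------- #


def _tree_layer_indices(spec: ArchitectureSpec) -> tuple[int, int, int, int]:
    kinds = tuple(type(l).__name__ for l in spec.layers)
    if kinds != ("ConvLayer", "PoolLayer", "TreeSamplingLayer", "FCLayer"):
        raise SingleRouteError(
            "pruned backward requires the single-route conv/pool/tree/FC "
            f"stack; got layer chain {kinds} (a fully connected or second "
            "convolutional stage admits multiple routes per weight)")
    return 0, 1, 2, 3


def backward_pruned(spec: ArchitectureSpec, params: NetworkParams,
                    trace: ActivationTrace, targets: np.ndarray) -> GradientSet:
    """Single-route gradients for tree architectures.

    Per sample, per weight application, the contribution is the product
    along the weight's unique route — input value, sigma' factors of the
    conv and tree units on the route, the downstream tree and readout
    weights, and the output error — summed over output units, branches and
    applications.  Routes blocked by an inactive ReLU unit or a
    non-selected pooling unit contribute exactly zero and are skipped.

    Numerically identical (to rounding) to :func:`backward_reference`;
    raises :class:`SingleRouteError` on non-tree specs.
    """
    _check_trace(params, trace)
    ic, ip, it, ifc = _tree_layer_indices(spec)
    conv: ConvLayer = spec.layers[ic]
    pool: PoolLayer = spec.layers[ip]
    tree: TreeSamplingLayer = spec.layers[it]
    fc: FCLayer = spec.layers[ifc]
    c, k, m = tree.channels, tree.depth, tree.branches
    j, r, sw = tree.slabs, tree.slab_rows, tree.in_w
    p = pool.size
    f = conv.kernel
    bsz = trace.batch_size
    report = loss_cross_entropy(trace, targets)
    err_all = report.error / bsz

    w_tree = params.weights[it].reshape(c, k, m, tree.in_h, sw)
    w_fc = _effective_fc_weight(fc, params.weights[ifc])

    sp_tree_all = trace.activation_derivative(it)              # (B, M*C*J)
    sp_conv_all = trace.activation_derivative(ic)              # (B, C*K, H', W')
    argmax = trace.pool_argmax[ip]                             # (B, C*K, sh, sw)

    d_conv = np.zeros_like(params.weights[ic])                 # (C*K, 1, f, f)
    d_tree = np.zeros_like(params.weights[it])
    d_fc = np.zeros_like(params.weights[ifc])
    d_tree5 = d_tree.reshape(c, k, m, tree.in_h, sw)

    for b in range(bsz):
        err = err_all[b]
        tree_post = trace.post[it][b]
        sp_tree = sp_tree_all[b]
        active_u = np.nonzero(sp_tree != 0.0)[0]
        if active_u.size == 0:
            continue
        # readout: d(W_fc[u, o]) = tree_post[u] * err[o], active units only
        d_fc[active_u] += np.outer(tree_post[active_u], err)
        # downstream factor at each active tree unit:
        #   g[u] = sigma'_tree[u] * sum_o W_fc[u, o] * err[o]
        g = np.zeros(tree.out_units)
        g[active_u] = sp_tree[active_u] * (w_fc[active_u] @ err)
        g3 = g.reshape(m, c, j)
        pooled = trace.post[ip][b].reshape(c, k, tree.in_h, sw)
        # tree weights: d(W_tree[c*K+k, m, row, col]) = pooled * g, active units
        mm, cc, jj = np.nonzero(g3 != 0.0)
        for mi, ci, ji in zip(mm, cc, jj):
            rows = slice(ji * r, (ji + 1) * r)
            d_tree5[ci, :, mi, rows, :] += pooled[ci, :, rows, :] * g3[mi, ci, ji]
        # conv weights: upstream-of-weight factor at a selected, active conv
        # unit (c, k, i, j) is
        #   t = sigma'_conv * sum_{m active} W_tree[cK+k, m, pi, pj] * g3[m, c, slab(pi)]
        # and the route contribution is input_patch * t.
        act_m = np.nonzero(g3.any(axis=(1, 2)))[0]             # branches with life
        x_in = trace.inputs[ic][b]
        for ci in range(c):
            # g replicated over the r rows of each slab -> (ma, sh, sw)
            grow = np.repeat(g3[act_m, ci, :], r, axis=1)
            gexp = np.broadcast_to(grow[:, :, None],
                                   (act_m.size, tree.in_h, sw))
            t_ck = np.einsum("kmiv,miv->kiv", w_tree[ci][:, act_m], gexp,
                             optimize=True)                    # (K, sh, sw)
            for ki in range(k):
                ch = ci * k + ki
                sel = _selected_mask(argmax[b, ch], p, sp_conv_all.shape[2:])
                active_pos = np.argwhere(sel & (sp_conv_all[b, ch] != 0.0))
                for (i, jx) in active_pos:
                    tval = sp_conv_all[b, ch, i, jx] * t_ck[ki, i // p, jx // p]
                    if tval == 0.0:
                        continue
                    d_conv[ch, 0] += x_in[ci, i:i + f, jx:jx + f] * tval
    if fc.mask is not None:
        d_fc *= fc.mask
    return GradientSet({ic: d_conv, it: d_tree, ifc: d_fc})


def _selected_mask(idx: np.ndarray, p: int,
                   conv_shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H', W') mask of conv positions selected by their pooling window."""
    h, w = conv_shape
    sel = np.zeros((h, w), dtype=bool)
    sh, sw = idx.shape
    rows = (np.arange(sh)[:, None] * p) + idx // p             # (sh, sw)
    cols = (np.arange(sw)[None, :] * p) + idx % p              # (sh, sw)
    sel[rows.ravel(), cols.ravel()] = True
    return sel


# --------------------------------------------------------------------------- #
# optimizer and schedules
# --------------------------------------------------------------------------- #


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters.

    ``lr`` is the base learning rate eta, ``momentum`` the Nesterov
    momentum constant mu, ``weight_decay`` the L2 constant alpha added to
    the gradient before the momentum update.  ``schedule`` is either
    ``("piecewise", [(start_epoch, eta), ...])`` or
    ``("multiplicative", factor, period_epochs)``; ``None`` keeps ``lr``
    constant.  ``weight_decay_schedule`` is an optional piecewise
    ``[(start_epoch, alpha), ...]`` override.
    """

    lr: float = 0.075
    momentum: float = 0.965
    weight_decay: float = 5e-5
    batch_size: int = 100
    epochs: int = 30
    schedule: tuple | None = None
    weight_decay_schedule: list[tuple[int, float]] | None = None
    seed: int = 0
    engine: str = "reference"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigurationError("learning rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ConfigurationError("weight decay must be >= 0")


#: Learning-rate schedules used for the full-scale offline runs.
SCHEDULES: dict[str, tuple] = {
    "lenet5_offline": ("piecewise", [(0, 0.01), (100, 0.005), (150, 0.001)]),
    "tree3_k6_m16": ("piecewise", [(0, 0.075), (50, 0.05), (70, 0.01),
                                   (100, 0.005), (150, 0.001), (175, 0.0001)]),
    "tree3_k15_m16": ("piecewise", [(0, 0.075), (50, 0.05), (70, 0.01),
                                    (100, 0.0075), (150, 0.003)]),
    "tree3_k15_m80": ("multiplicative", 0.6, 20),
}


def lr_schedule(config: TrainingConfig, epoch: int) -> float:
    """Learning rate at ``epoch`` under the config's schedule.

    Piecewise schedules hold their last value beyond the declared range;
    the multiplicative schedule is ``lr * factor**(epoch // period)``.
    """
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    sched = config.schedule
    if sched is None:
        return config.lr
    if sched[0] == "piecewise":
        pieces = sorted(sched[1])
        eta = pieces[0][1]
        for start, value in pieces:
            if epoch >= start:
                eta = value
        return float(eta)
    if sched[0] == "multiplicative":
        factor, period = sched[1], sched[2]
        return float(config.lr * factor ** (epoch // period))
    raise ConfigurationError(f"unknown schedule kind {sched[0]!r}")


def weight_decay_at(config: TrainingConfig, epoch: int) -> float:
    alpha = config.weight_decay
    if config.weight_decay_schedule:
        for start, value in sorted(config.weight_decay_schedule):
            if epoch >= start:
                alpha = value
    return float(alpha)


@dataclass
class OptState:
    """Nesterov-momentum velocity buffers."""

    velocity: dict[int, np.ndarray] = field(default_factory=dict)


def sgd_step(params: NetworkParams, grads: GradientSet, config: TrainingConfig,
             state: OptState | None = None, lr: float | None = None,
             weight_decay: float | None = None) -> tuple[NetworkParams, OptState]:
    """One SGD step with Nesterov momentum and L2 weight decay (in place).

        d = g + alpha * w
        v = mu * v + d
        w = w - eta * (d + mu * v)        (plain  w = w - eta * v  if mu = 0)

    which is the standard look-ahead form with the decay added to the
    gradient before the momentum update.
    """
    if state is None:
        state = OptState()
    eta = config.lr if lr is None else lr
    mu = config.momentum
    alpha = config.weight_decay if weight_decay is None else weight_decay
    for i, w in params.weights.items():
        g = grads.grads[i]
        if g.shape != w.shape:
            raise ConfigurationError(
                f"gradient shape {g.shape} != weight shape {w.shape} at layer {i}")
        d = g + alpha * w if alpha else g
        v = state.velocity.get(i)
        if v is None:
            v = np.zeros_like(w)
            state.velocity[i] = v
        if mu:
            v *= mu
            v += d
            w -= eta * (d + mu * v)
        else:
            w -= eta * d
    return params, state


# --------------------------------------------------------------------------- #
# training loop
# --------------------------------------------------------------------------- #


def evaluate(spec: ArchitectureSpec, params: NetworkParams,
             images: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(accuracy, mean cross-entropy) on a labelled set."""
    trace = forward(spec, params, images)
    report = loss_cross_entropy(trace, labels)
    acc = float((trace.probs.argmax(axis=1) == np.asarray(labels)).mean())
    return acc, report.value


def train(spec: ArchitectureSpec, params: NetworkParams, config: TrainingConfig,
          train_images: np.ndarray, train_labels: np.ndarray,
          test_images: np.ndarray | None = None,
          test_labels: np.ndarray | None = None,
          pruning_policy=None,
          callback: Callable[[dict], None] | None = None,
          ) -> tuple[NetworkParams, list[dict]]:
    """Mini-batch SGD training, deterministic given ``config.seed``.

    ``config.engine`` selects the backward pass (``"reference"`` or
    ``"pruned"``).  ``pruning_policy`` (a :class:`~treebp.sparsity.
    PruningPolicy`) is applied to every mini-batch gradient before the
    update.  Returns the trained parameters and one metrics row per epoch
    (epoch, lr, train_loss, train_accuracy, test_accuracy).
    """
    from .sparsity import apply_threshold_pruning  # local: avoid cycle

    backward = {"reference": backward_reference, "pruned": backward_pruned}[config.engine]
    rng = np.random.default_rng(config.seed)
    n = train_images.shape[0]
    history: list[dict] = []
    state = OptState()
    for epoch in range(config.epochs):
        eta = lr_schedule(config, epoch)
        alpha = weight_decay_at(config, epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, yb = train_images[sel], train_labels[sel]
            trace = forward(spec, params, xb)
            grads = backward(spec, params, trace, yb)
            if pruning_policy is not None:
                grads, _ = apply_threshold_pruning(grads, pruning_policy)
            params, state = sgd_step(params, grads, config, state,
                                     lr=eta, weight_decay=alpha)
            losses.append(loss_cross_entropy(trace, yb).value)
        row = {
            "epoch": epoch,
            "lr": eta,
            "train_loss": float(np.mean(losses)),
        }
        acc, _ = evaluate(spec, params, train_images, train_labels)
        row["train_accuracy"] = acc
        if test_images is not None:
            tacc, tloss = evaluate(spec, params, test_images, test_labels)
            row["test_accuracy"] = tacc
            row["test_loss"] = tloss
        history.append(row)
        if callback is not None:
            callback(row)
    return params, history
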