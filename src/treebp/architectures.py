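"""Architecture specifications, shape inference and parameter initialization.

Three architectures are instantiable:

* **Tree-3** — grouped 5x5 convolution (K filters per input channel, shared
  across M branches), 2x2 max-pooling, a "tree sampling" layer that tiles
  each pooled map into non-overlapping slabs of ``r`` consecutive rows (all
  columns, summed over the K depth filters, with private per-branch
  weights), and a fully connected readout.
* **ten-Tree-3** — ten single-output Tree-3 heads sharing one convolutional
  layer; realized as one tree network with ``10*M`` branches and a
  block-diagonal readout mask, so each output unit sees only the branches
  of its own head.
* **LeNet-5** — the classical conv/pool/conv/pool/FC(120)/FC(84)/FC(10)
  stack, kept as the multi-route reference architecture for path counting.

Weights are He-normal initialized: zero-mean Gaussian with standard
deviation ``sqrt(2 / fan_in)`` per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ConfigurationError",
    "Tree3Config",
    "ConvLayer",
    "PoolLayer",
    "TreeSamplingLayer",
    "FCLayer",
    "ArchitectureSpec",
    "NetworkParams",
    "build_tree3",
    "build_lenet5",
    "build_ten_tree3",
    "init_params",
    "count_gradient_instances",
    "he_std",
]


class ConfigurationError(ValueError):
    """Raised for geometrically impossible or inconsistent architecture configs."""


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Tree3Config:
    """Geometry and hyper-structure of a Tree-3 network.

    Parameters
    ----------
    channels
        Input channels C (3 for RGB, 1 for grayscale).
    filters_per_channel
        K, the number of 5x5 filters convolved with each input channel.
    branches
        M, the number of parallel dendrite-like branches.  All branches
        share the same C*K convolutional filters but own private tree and
        readout weights.
    height, width
        Input image size in pixels.
    filter_size
        Convolution filter side f (default 5).
    pool_size
        Max-pooling window side p (default 2, non-overlapping).
    slab_rows
        r, the number of consecutive pooled rows aggregated by one tree
        unit (2 for the 32x32 RGB geometry, 4 for the 28x28 grayscale one).
    classes
        Number of output units.
    activation
        ``"relu"`` or ``"sigmoid"`` for both hidden layers.
    single_output
        Marks a one-output head used inside the ten-tree variant.
    """

    channels: int = 3
    filters_per_channel: int = 6
    branches: int = 16
    height: int = 32
    width: int = 32
    filter_size: int = 5
    pool_size: int = 2
    slab_rows: int = 2
    classes: int = 10
    activation: str = "relu"
    single_output: bool = False

    def __post_init__(self) -> None:
        if self.channels < 1 or self.filters_per_channel < 1 or self.branches < 1:
            raise ConfigurationError(
                "channels, filters_per_channel and branches must all be >= 1"
            )
        if self.classes < 2 and not self.single_output:
            raise ConfigurationError("classes must be >= 2")
        if self.activation not in ("relu", "sigmoid"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        ch, cw = self.conv_out
        if ch < 1 or cw < 1:
            raise ConfigurationError(
                f"input {self.height}x{self.width} too small for a "
                f"{self.filter_size}x{self.filter_size} filter"
            )
        if ch % self.pool_size or cw % self.pool_size:
            raise ConfigurationError(
                f"conv output {ch}x{cw} is not divisible by the pool size "
                f"{self.pool_size} (offending dimension: "
                f"{'height' if ch % self.pool_size else 'width'})"
            )
        ph, _ = self.pooled
        if ph % self.slab_rows:
            raise ConfigurationError(
                f"pooled height {ph} is not divisible by slab_rows "
                f"{self.slab_rows}"
            )

    @property
    def conv_out(self) -> tuple[int, int]:
        f = self.filter_size
        return self.height - f + 1, self.width - f + 1

    @property
    def pooled(self) -> tuple[int, int]:
        ch, cw = self.conv_out
        return ch // self.pool_size, cw // self.pool_size

    @property
    def slabs_per_map(self) -> int:
        """J, the number of tree units per (branch, channel)."""
        return self.pooled[0] // self.slab_rows


# --------------------------------------------------------------------------- #
# layer descriptors
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ConvLayer:
    """2-D valid convolution (cross-correlation), optionally grouped.

    ``branch_replication`` records how many logical branches share this
    filter bank (M for the Tree-3 conv, 1 otherwise); it enters gradient-
    instance accounting and path analysis, never the forward pass.
    """

    in_channels: int
    out_channels: int
    kernel: int
    groups: int = 1
    activation: str = "relu"
    branch_replication: int = 1

    @property
    def weight_shape(self) -> tuple[int, ...]:
        return (self.out_channels, self.in_channels // self.groups,
                self.kernel, self.kernel)

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, h, w = in_shape
        if c != self.in_channels:
            raise ConfigurationError(
                f"conv expects {self.in_channels} input channels, got {c}")
        return (self.out_channels, h - self.kernel + 1, w - self.kernel + 1)


@dataclass(frozen=True)
class PoolLayer:
    """Non-overlapping max-pooling with a square window."""

    size: int = 2

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        c, h, w = in_shape
        if h % self.size or w % self.size:
            raise ConfigurationError(
                f"pool input {h}x{w} not divisible by window {self.size}")
        return (c, h // self.size, w // self.size)


@dataclass(frozen=True)
class TreeSamplingLayer:
    """Per-branch slab aggregation of pooled maps.

    Input is the (C*K, s_h, s_w) pooled stack.  For branch m, channel c and
    slab j the output unit is

        pre[m, c, j] = sum_k sum_{row in slab j} sum_col
                           W[c*K + k, m, row, col] * pooled[c*K + k, row, col]

    where slab j covers rows ``[j*r, (j+1)*r)`` and all columns.  Weights
    are private per (branch, position) and shared over nothing; the sum
    over the K depth filters mirrors the depth summation of a second
    convolutional layer.  Output units are ordered branch-major:
    flat index = m*(C*J) + c*J + j.
    """

    channels: int        # C
    depth: int           # K
    branches: int        # M (total; 10*M for the ten-tree variant)
    in_h: int
    in_w: int
    slab_rows: int       # r
    activation: str = "relu"

    @property
    def slabs(self) -> int:
        return self.in_h // self.slab_rows

    @property
    def weight_shape(self) -> tuple[int, ...]:
        return (self.channels * self.depth, self.branches, self.in_h, self.in_w)

    @property
    def out_units(self) -> int:
        return self.branches * self.channels * self.slabs

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        expected = (self.channels * self.depth, self.in_h, self.in_w)
        if tuple(in_shape) != expected:
            raise ConfigurationError(
                f"tree sampling expects input {expected}, got {tuple(in_shape)}")
        return (self.out_units,)


@dataclass(frozen=True)
class FCLayer:
    """Fully connected layer; ``mask`` (if given) zeroes forbidden edges."""

    in_features: int
    out_features: int
    activation: str = "linear"
    mask: np.ndarray | None = field(default=None, compare=False, repr=False)

    @property
    def weight_shape(self) -> tuple[int, ...]:
        return (self.in_features, self.out_features)

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        n = int(np.prod(in_shape))
        if n != self.in_features:
            raise ConfigurationError(
                f"FC expects {self.in_features} inputs, got {n}")
        return (self.out_features,)


Layer = ConvLayer | PoolLayer | TreeSamplingLayer | FCLayer


# --------------------------------------------------------------------------- #
# architecture spec
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered, shape-checked chain of layers.

    ``family`` tags the construction (``tree3`` / ``ten_tree3`` /
    ``lenet5``); engines and analyzers dispatch on it.  ``heads`` is the
    number of independent readout heads (10 for ten-Tree-3, else 1).
    """

    input_shape: tuple[int, int, int]
    layers: tuple[Layer, ...]
    family: str = "custom"
    config: Tree3Config | None = None
    heads: int = 1

    def __post_init__(self) -> None:
        # chain compatibility is enforced eagerly so a spec is valid by construction
        self.shapes()

    def shapes(self) -> list[tuple[int, ...]]:
        """Per-layer output shapes, starting from the input shape."""
        out: list[tuple[int, ...]] = [self.input_shape]
        shape: tuple[int, ...] = self.input_shape
        for layer in self.layers:
            shape = layer.out_shape(shape)
            out.append(shape)
        return out

    @property
    def out_features(self) -> int:
        return int(np.prod(self.shapes()[-1]))

    def weighted_layers(self) -> Iterator[tuple[int, Layer]]:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, (ConvLayer, TreeSamplingLayer, FCLayer)):
                yield i, layer

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(l.weight_shape)) for _, l in self.weighted_layers())

    def describe(self) -> str:
        """Shape table: one row per layer with weight/input/output sizes."""
        shapes = self.shapes()
        rows = [("Type", "Weight size", "Input size", "Output size")]
        for i, layer in enumerate(self.layers):
            in_s = "x".join(map(str, shapes[i]))
            out_s = "x".join(map(str, shapes[i + 1]))
            if isinstance(layer, ConvLayer):
                if layer.groups > 1:
                    # grouped filters read as C x K x f x f with C groups
                    w = (f"{layer.groups}x{layer.out_channels // layer.groups}"
                         f"x{layer.kernel}x{layer.kernel} groups={layer.groups}")
                else:
                    w = "x".join(map(str, layer.weight_shape))
                name = "Conv2d"
            elif isinstance(layer, PoolLayer):
                w, name = f"{layer.size}x{layer.size}", "MaxPool2d"
            elif isinstance(layer, TreeSamplingLayer):
                w, name = "x".join(map(str, layer.weight_shape)), "Tree Sampling"
            else:
                w, name = "x".join(map(str, layer.weight_shape)), "FC"
            rows.append((name, w, in_s, out_s))
        widths = [max(len(r[i]) for r in rows) for i in range(4)]
        return "\n".join(
            "  ".join(col.ljust(widths[i]) for i, col in enumerate(row)).rstrip()
            for row in rows
        )


# --------------------------------------------------------------------------- #
# builders
# --------------------------------------------------------------------------- #


def build_tree3(config: Tree3Config) -> ArchitectureSpec:
    """Instantiate the Tree-3 architecture for a :class:`Tree3Config`.

    The canonical 32x32 RGB geometry (C=3, K=6, M=16, r=2) yields
    conv 3K x 28 x 28, pooled 3K x 14 x 14, tree output 3M x 7 = 336 units
    and a (21M x 10) readout.
    """
    c = config
    ph, pw = c.pooled
    layers: tuple[Layer, ...] = (
        ConvLayer(
            in_channels=c.channels,
            out_channels=c.channels * c.filters_per_channel,
            kernel=c.filter_size,
            groups=c.channels,
            activation=c.activation,
            branch_replication=c.branches,
        ),
        PoolLayer(c.pool_size),
        TreeSamplingLayer(
            channels=c.channels,
            depth=c.filters_per_channel,
            branches=c.branches,
            in_h=ph,
            in_w=pw,
            slab_rows=c.slab_rows,
            activation=c.activation,
        ),
        FCLayer(
            in_features=c.branches * c.channels * (ph // c.slab_rows),
            out_features=1 if c.single_output else c.classes,
            activation="linear",
        ),
    )
    return ArchitectureSpec(
        input_shape=(c.channels, c.height, c.width),
        layers=layers,
        family="tree3",
        config=c,
    )


def build_ten_tree3(config: Tree3Config) -> ArchitectureSpec:
    """Ten single-output Tree-3 heads sharing one convolutional layer.

    Realized as a single tree network whose tree-sampling layer carries
    ``10 * M`` branches; the readout weight is (C*J*10M, 10) under a
    block-diagonal mask, so output unit h is fed only by the branches of
    head h.  The ten scalar head outputs feed one softmax.
    """
    c = config
    if not c.single_output:
        raise ConfigurationError("ten-tree requires single_output=True heads")
    if c.classes != 10:
        raise ConfigurationError(
            f"ten-tree is a 10-way readout; got classes={c.classes}")
    heads = 10
    ph, pw = c.pooled
    j = ph // c.slab_rows
    per_head = c.branches * c.channels * j          # tree units owned by one head
    total_units = heads * per_head
    mask = np.zeros((total_units, heads))
    for h in range(heads):
        mask[h * per_head:(h + 1) * per_head, h] = 1.0
    layers: tuple[Layer, ...] = (
        ConvLayer(
            in_channels=c.channels,
            out_channels=c.channels * c.filters_per_channel,
            kernel=c.filter_size,
            groups=c.channels,
            activation=c.activation,
            branch_replication=heads * c.branches,
        ),
        PoolLayer(c.pool_size),
        TreeSamplingLayer(
            channels=c.channels,
            depth=c.filters_per_channel,
            branches=heads * c.branches,
            in_h=ph,
            in_w=pw,
            slab_rows=c.slab_rows,
            activation=c.activation,
        ),
        FCLayer(
            in_features=total_units,
            out_features=heads,
            activation="linear",
            mask=mask,
        ),
    )
    return ArchitectureSpec(
        input_shape=(c.channels, c.height, c.width),
        layers=layers,
        family="ten_tree3",
        config=c,
        heads=heads,
    )


def build_lenet5(input_shape: tuple[int, int, int] = (3, 32, 32),
                 classes: int = 10) -> ArchitectureSpec:
    """The five-hidden-layer convolutional LeNet-5 reference architecture.

    conv(6 @ 5x5) -> pool(2x2) -> conv(16 @ 5x5) -> pool(2x2) ->
    FC 400 -> FC 120 -> FC 84 -> FC ``classes``.  The first convolution
    mixes all input channels (filters of depth C); ReLU throughout the
    hidden layers.  Only the 32x32 geometry flattens to the classical
    400-unit layer.
    """
    c, h, w = input_shape
    if (h, w) != (32, 32):
        raise ConfigurationError(
            f"LeNet-5 requires a 32x32 input geometry, got {h}x{w}")
    layers: tuple[Layer, ...] = (
        ConvLayer(in_channels=c, out_channels=6, kernel=5, activation="relu"),
        PoolLayer(2),
        ConvLayer(in_channels=6, out_channels=16, kernel=5, activation="relu"),
        PoolLayer(2),
        FCLayer(400, 120, activation="relu"),
        FCLayer(120, 84, activation="relu"),
        FCLayer(84, classes, activation="linear"),
    )
    return ArchitectureSpec(input_shape=input_shape, layers=layers,
                            family="lenet5")


# --------------------------------------------------------------------------- #
# initialization
# --------------------------------------------------------------------------- #


def he_std(layer: Layer) -> float:
    """He-normal target standard deviation, ``sqrt(2 / fan_in)``.

    fan_in is the number of inputs feeding one output unit: per-group
    ``in_channels * k**2`` for conv, ``K * r * columns`` for tree sampling,
    the in-degree for FC (mask-aware).
    """
    if isinstance(layer, ConvLayer):
        fan_in = (layer.in_channels // layer.groups) * layer.kernel ** 2
    elif isinstance(layer, TreeSamplingLayer):
        fan_in = layer.depth * layer.slab_rows * layer.in_w
    elif isinstance(layer, FCLayer):
        if layer.mask is not None:
            fan_in = int(layer.mask.sum(axis=0).max())
        else:
            fan_in = layer.in_features
    else:
        raise ConfigurationError(f"{type(layer).__name__} has no weights")
    return float(np.sqrt(2.0 / fan_in))


@dataclass
class NetworkParams:
    """All weight tensors of one network plus the initialization record."""

    weights: dict[int, np.ndarray]
    seed: int
    scheme: str = "he_normal"

    def copy(self) -> "NetworkParams":
        return NetworkParams({i: w.copy() for i, w in self.weights.items()},
                             self.seed, self.scheme)

    def fingerprint(self) -> tuple:
        """Cheap content token used to detect stale activation traces."""
        return tuple(
            (i, w.shape, float(w.sum()), float(abs(w).sum()))
            for i, w in sorted(self.weights.items())
        )


def init_params(spec: ArchitectureSpec, seed: int) -> NetworkParams:
    """He-normal initialization, deterministic given ``seed``.

    Each weighted layer draws from an independent stream of one seeded
    generator in layer order; masked FC entries are zeroed.
    """
    rng = np.random.default_rng(seed)
    weights: dict[int, np.ndarray] = {}
    for i, layer in spec.weighted_layers():
        w = rng.normal(0.0, he_std(layer), size=layer.weight_shape)
        if isinstance(layer, FCLayer) and layer.mask is not None:
            w = w * layer.mask
        weights[i] = w
    return NetworkParams(weights=weights, seed=seed)


# --------------------------------------------------------------------------- #
# structural counting
# --------------------------------------------------------------------------- #


def count_gradient_instances(spec: ArchitectureSpec, layer_index: int,
                             post_pooling: bool = False) -> int:
    """Number of per-application weight-gradient terms of a weighted layer.

    A gradient *instance* is one application of one weight: filter position
    x channel x filter x application position x branch.  For a conv layer
    this is ``prod(weight shape) * output positions * branch replication``;
    tree-sampling and FC weights are applied once each, so their instance
    count equals their weight count (mask-aware for a masked readout).

    With ``post_pooling=True`` (conv followed by max-pooling) only the one
    selected application per pooling window is counted, dividing the
    application positions by ``p**2``.
    """
    try:
        layer = spec.layers[layer_index]
    except IndexError:
        raise ConfigurationError(f"no layer at index {layer_index}") from None
    shapes = spec.shapes()
    if isinstance(layer, ConvLayer):
        _, oh, ow = layer.out_shape(shapes[layer_index])
        positions = oh * ow
        if post_pooling:
            nxt = spec.layers[layer_index + 1] if layer_index + 1 < len(spec.layers) else None
            if not isinstance(nxt, PoolLayer):
                raise ConfigurationError(
                    "post_pooling counting requires a pooling layer after the conv")
            positions //= nxt.size ** 2
        return int(np.prod(layer.weight_shape)) * positions * layer.branch_replication
    if post_pooling:
        raise ConfigurationError("post_pooling applies to conv layers only")
    if isinstance(layer, TreeSamplingLayer):
        return int(np.prod(layer.weight_shape))
    if isinstance(layer, FCLayer):
        if layer.mask is not None:
            return int(layer.mask.sum())
        return int(np.prod(layer.weight_shape))
    raise ConfigurationError(
        f"layer {layer_index} ({type(layer).__name__}) has no weights")
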