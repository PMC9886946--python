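"""Route enumeration in layered connectivity DAGs.

A *route* is a directed chain of weight applications from a first-layer
unit (equivalently, from any weight applied at that unit — the downstream
routes coincide) to an output unit.  In the tree architectures every layer
after the input is a funnel, so each (unit, output) pair has exactly one
route; in LeNet-5 the second convolution and the fully connected stack
multiply routes into the millions.

Two counting conventions are deliberately kept side by side:

* **exact-dag** — exact enumeration by memoized dynamic programming,
  ``count(node) = sum over successors``; pooling nodes are single-selection
  funnels (each pooled unit is one node and a path enters it through one
  window member), so pooling does not divide exact route counts.
* **paper-closed-form** — the published LeNet-5 arithmetic
  ``16 x 25 / 4 = 100`` routes after pooling and
  ``100 x 120 x 84 = 1,008,000`` in total, which treats the 2x2 pooling as
  dividing the route count by 4.  The division is an approximation — exact
  window-overlap enumeration gives 400, not 100 — and the two conventions
  are reported under explicit tags, never merged.

Certification runs on the *per-branch logical DAG*: the convolutional
filters are physically shared across the M branches, so the physical graph
would give M routes per shared filter weight; each branch owns its logical
conv instance (the dendrite-like picture), and the report states the
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .architectures import (
    ArchitectureSpec,
    ConfigurationError,
    ConvLayer,
    FCLayer,
    PoolLayer,
    TreeSamplingLayer,
)

__all__ = [
    "ConnectivityDAG",
    "PathCountReport",
    "SingleRouteReport",
    "PaperLeNetRouteCount",
    "connectivity_dag",
    "count_paths_exact",
    "count_paths_paper_lenet5",
    "certify_single_route",
    "first_layer_route_counts",
]

Node = Hashable


@dataclass
class ConnectivityDAG:
    """Unit-level connectivity graph.

    ``succ`` maps every node to its successors (empty tuple for sinks);
    edges are weight applications, pooling funnels and readout fan-out.
    """

    succ: dict[Node, tuple[Node, ...]]
    outputs: tuple[Node, ...]
    convention: str = "exact-dag"

    @property
    def n_nodes(self) -> int:
        return len(self.succ)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.succ.values())


@dataclass
class PathCountReport:
    """Route counts between a source selection and the output units."""

    source: Node
    per_output: dict[Node, int]
    total: int
    convention: str


@dataclass
class SingleRouteReport:
    """Outcome of single-route certification on the per-branch logical DAG."""

    certified: bool
    max_count: int
    min_count: int
    witness: tuple[Node, int]
    convention: str = "per-branch logical DAG (each branch owns its conv instance)"
    note: str = ""


# --------------------------------------------------------------------------- #
# exact counting on explicit DAGs
# --------------------------------------------------------------------------- #


def count_paths_exact(dag: ConnectivityDAG, source: Node, output: Node) -> int:
    """Exact number of distinct directed paths from ``source`` to ``output``.

    Memoized DP over the DAG (iterative, so deep graphs do not hit the
    recursion limit).  ``source == output`` counts the empty path (1).
    """
    if source not in dag.succ:
        raise ConfigurationError(f"source node {source!r} not in DAG")
    if output not in dag.succ:
        raise ConfigurationError(f"output node {output!r} not in DAG")
    memo: dict[Node, int] = {output: 1}
    stack: list[tuple[Node, bool]] = [(source, False)]
    while stack:
        node, expanded = stack.pop()
        if node in memo:
            continue
        succ = dag.succ[node]
        if expanded:
            memo[node] = sum(memo[s] for s in succ)
        else:
            stack.append((node, True))
            for s in succ:
                if s not in memo:
                    stack.append((s, False))
    return memo[source]


# --------------------------------------------------------------------------- #
# DAG construction
# --------------------------------------------------------------------------- #


def connectivity_dag(spec: ArchitectureSpec,
                     include_input: bool = False) -> ConnectivityDAG:
    """Build the unit-level connectivity DAG of a spec.

    For tree-family specs the per-branch logical graph is built (node tags
    carry the branch index).  ``include_input=True`` adds input-pixel nodes
    with one edge per weight application into the first layer; intended for
    small geometries, since those edges dominate the graph size.
    """
    if spec.family in ("tree3", "ten_tree3"):
        return _tree_dag(spec, include_input)
    if spec.family == "lenet5":
        return _lenet_dag(spec, include_input)
    raise ConfigurationError(
        f"no DAG builder for architecture family {spec.family!r}")


def _tree_dag(spec: ArchitectureSpec, include_input: bool) -> ConnectivityDAG:
    conv: ConvLayer = spec.layers[0]
    pool: PoolLayer = spec.layers[1]
    tree: TreeSamplingLayer = spec.layers[2]
    fc: FCLayer = spec.layers[3]
    c, k, m = tree.channels, tree.depth, tree.branches
    j, r = tree.slabs, tree.slab_rows
    f, p = conv.kernel, pool.size
    _, ch, cw = conv.out_shape(spec.input_shape)
    succ: dict[Node, tuple[Node, ...]] = {}
    outputs = tuple(("out", o) for o in range(fc.out_features))
    for o in outputs:
        succ[o] = ()
    if fc.mask is not None:
        per_head = fc.in_features // spec.heads
    for mi in range(m):
        for ci in range(c):
            for ji in range(j):
                u = mi * (c * j) + ci * j + ji
                if fc.mask is not None:
                    outs = tuple(("out", o) for o in range(fc.out_features)
                                 if fc.mask[u, o])
                else:
                    outs = outputs
                succ[("tree", mi, ci, ji)] = outs
            for ki in range(k):
                for pi in range(ch // p):
                    for pj in range(cw // p):
                        succ[("pool", mi, ci, ki, pi, pj)] = (
                            ("tree", mi, ci, pi // r),)
                for i in range(ch):
                    for jx in range(cw):
                        succ[("conv", mi, ci, ki, i, jx)] = (
                            ("pool", mi, ci, ki, i // p, jx // p),)
    if include_input:
        _, h, w = spec.input_shape
        for ci in range(c):
            for y in range(h):
                for x in range(w):
                    targets = [
                        ("conv", mi, ci, ki, i, jx)
                        for mi in range(m) for ki in range(k)
                        for i in range(max(0, y - f + 1), min(ch - 1, y) + 1)
                        for jx in range(max(0, x - f + 1), min(cw - 1, x) + 1)
                    ]
                    succ[("in", ci, y, x)] = tuple(targets)
    return ConnectivityDAG(succ=succ, outputs=outputs)


def _lenet_dag(spec: ArchitectureSpec, include_input: bool) -> ConnectivityDAG:
    conv1: ConvLayer = spec.layers[0]
    conv2: ConvLayer = spec.layers[2]
    fc_widths = [l.out_features for l in spec.layers[4:]]
    cin, h, w = spec.input_shape
    f = conv1.kernel
    c1h, c1w = h - f + 1, w - f + 1                      # 28 x 28
    p1h, p1w = c1h // 2, c1w // 2                        # 14 x 14
    c2h, c2w = p1h - f + 1, p1w - f + 1                  # 10 x 10
    p2h, p2w = c2h // 2, c2w // 2                        # 5 x 5
    n1, n2 = conv1.out_channels, conv2.out_channels
    succ: dict[Node, tuple[Node, ...]] = {}
    outputs = tuple(("out", o) for o in range(fc_widths[-1]))
    for o in outputs:
        succ[o] = ()
    # fully connected chain (hidden widths then output)
    prev = [("flat", g, pi, pj) for g in range(n2)
            for pi in range(p2h) for pj in range(p2w)]
    layer_nodes = [prev]
    for li, width in enumerate(fc_widths[:-1]):
        layer_nodes.append([("fc", li, n) for n in range(width)])
    layer_nodes.append(list(outputs))
    for cur, nxt in zip(layer_nodes[:-2], layer_nodes[1:-1]):
        for node in cur:
            succ[node] = tuple(nxt)
    for node in layer_nodes[-2]:
        succ[node] = outputs
    # conv2 -> pool2 (= flat)
    for g in range(n2):
        for i in range(c2h):
            for jx in range(c2w):
                succ[("conv2", g, i, jx)] = (("flat", g, i // 2, jx // 2),)
    # pool1 -> conv2: every filter, every application covering the unit
    for fch in range(n1):
        for y in range(p1h):
            for x in range(p1w):
                targets = tuple(
                    ("conv2", g, i, jx)
                    for g in range(n2)
                    for i in range(max(0, y - f + 1), min(c2h - 1, y) + 1)
                    for jx in range(max(0, x - f + 1), min(c2w - 1, x) + 1)
                )
                succ[("pool1", fch, y, x)] = targets
    # conv1 -> pool1
    for fch in range(n1):
        for i in range(c1h):
            for jx in range(c1w):
                succ[("conv1", fch, i, jx)] = (("pool1", fch, i // 2, jx // 2),)
    if include_input:
        for ci in range(cin):
            for y in range(h):
                for x in range(w):
                    targets = tuple(
                        ("conv1", fch, i, jx)
                        for fch in range(n1)
                        for i in range(max(0, y - f + 1), min(c1h - 1, y) + 1)
                        for jx in range(max(0, x - f + 1), min(c1w - 1, x) + 1)
                    )
                    succ[("in", ci, y, x)] = targets
    return ConnectivityDAG(succ=succ, outputs=outputs)


# --------------------------------------------------------------------------- #
# layered DP over whole architectures
# --------------------------------------------------------------------------- #


def first_layer_route_counts(spec: ArchitectureSpec) -> dict:
    """Exact per-(first-layer unit, output) route counts by layered DP.

    Exploits the layered regularity of the supported families so the full
    CIFAR-scale geometries certify in milliseconds; exactly equivalent to
    :func:`count_paths_exact` on the explicit DAG (cross-checked in the
    test suite on small geometries).

    Returns a dict with ``max_count``, ``min_count``, ``witness`` (a
    first-layer unit label and output index attaining the max) and
    ``counts`` — an array of per-pair counts over a reduced index set that
    tiles the first layer (counts are constant over indices the DP never
    splits, e.g. columns within a pooled row).
    """
    if spec.family in ("tree3", "ten_tree3"):
        tree: TreeSamplingLayer = spec.layers[2]
        fc: FCLayer = spec.layers[3]
        m, c, j = tree.branches, tree.channels, tree.slabs
        o = fc.out_features
        if fc.mask is not None:
            tcounts = fc.mask.reshape(m, c, j, o).astype(np.int64)
        else:
            tcounts = np.ones((m, c, j, o), dtype=np.int64)
        # pool unit (m, c, k, row, col) -> its slab's tree unit; conv unit
        # (m, c, k, i, jx) -> its pooling window's pooled unit.  Neither step
        # splits routes, so first-layer counts equal the slab's tree counts.
        counts = np.repeat(tcounts, tree.slab_rows, axis=2)    # per pooled row
        flat = counts.reshape(-1, o)
        hi = int(flat.max())
        lo = int(flat.min())
        p = spec.layers[1].size
        mi_, ci_, ri_, oi = np.unravel_index(int(counts.argmax()), counts.shape)
        witness = (("conv", int(mi_), int(ci_), 0, int(ri_) * p, 0), int(oi))
        return {"max_count": hi, "min_count": lo, "witness": witness,
                "counts": counts,
                "index": "(branch, channel, pooled row; constant over k, "
                         "columns and within-window position)"}
    if spec.family == "lenet5":
        conv2: ConvLayer = spec.layers[2]
        fc_widths = [l.out_features for l in spec.layers[4:]]
        f = conv2.kernel
        _, h, w = spec.input_shape
        p1h = (h - f + 1) // 2
        c2h = p1h - f + 1
        per_flat = int(np.prod(fc_widths[:-1]))                # 120*84
        # coverage: number of conv2 application rows containing pooled row y
        cov1 = np.array([min(y, c2h - 1) - max(0, y - f + 1) + 1
                         for y in range(p1h)], dtype=np.int64)
        cov = cov1[:, None] * cov1[None, :]                    # (14, 14)
        counts = cov * conv2.out_channels * per_flat           # per pool1 unit
        counts = np.repeat(counts[None, :, :], spec.layers[0].out_channels,
                           axis=0)
        counts = counts[..., None] * np.ones(fc_widths[-1], dtype=np.int64)
        hi = int(counts.max())
        lo = int(counts.min())
        fi, yi, xi, oi = np.unravel_index(int(counts.argmax()), counts.shape)
        witness = (("conv1", int(fi), int(yi) * 2, int(xi) * 2), int(oi))
        return {"max_count": hi, "min_count": lo, "witness": witness,
                "counts": counts,
                "index": "(filter, pooled row, pooled col, output; constant "
                         "within pooling windows)"}
    raise ConfigurationError(
        f"no layered route counter for family {spec.family!r}")


def certify_single_route(spec: ArchitectureSpec) -> SingleRouteReport:
    """Certify that every (first-layer unit, output) pair has one route.

    Runs the exact layered DP on the per-branch logical DAG.  For the
    plain Tree-3 the certificate requires every pair to have exactly one
    route; for the ten-head variant each unit reaches the one output of
    its own head (other pairs have zero routes by construction), so the
    certificate requires the maximum to be one and every within-head pair
    to be connected.
    """
    res = first_layer_route_counts(spec)
    hi, lo = res["max_count"], res["min_count"]
    note = ""
    if spec.family == "ten_tree3":
        counts = res["counts"]
        within = counts.max(axis=-1)   # best output per unit == its own head
        certified = hi == 1 and int(within.min()) == 1
        note = ("multi-head readout: cross-head pairs have zero routes by "
                "construction; certification checks within-head pairs")
    else:
        certified = hi == 1 and lo == 1
    witness = res["witness"]
    if certified:
        note = note or "single-route property holds for every pair"
    else:
        note = note or (
            f"unit {witness[0]} reaches output {witness[1]} via {hi} routes")
    return SingleRouteReport(certified=certified, max_count=hi, min_count=lo,
                             witness=witness, note=note)


# --------------------------------------------------------------------------- #
# the published closed form
# --------------------------------------------------------------------------- #


@dataclass
class PaperLeNetRouteCount:
    """Stepwise closed-form route arithmetic for a LeNet-5 first-layer unit.

    A first-hidden-layer unit feeds up to 25 applications of each of the
    16 second-layer filters (16 x 25 = 400); the closed form divides by
    the 2x2 pooling window area (16 x 25 / 4 = 100) and multiplies by the
    fully connected widths (100 x 120 x 84 = 1,008,000).  The pooling
    division is an approximation kept verbatim under this convention;
    exact DAG enumeration does not divide (see
    :func:`first_layer_route_counts`).
    """

    second_conv_filters: int = 16
    applications_per_unit: int = 25
    pool_window: int = 4
    fc_widths: tuple[int, ...] = (120, 84)
    routes_before_pooling: int = field(init=False)
    routes_after_pooling: int = field(init=False)
    total: int = field(init=False)
    convention: str = "paper-closed-form"

    def __post_init__(self) -> None:
        self.routes_before_pooling = (
            self.second_conv_filters * self.applications_per_unit)
        self.routes_after_pooling = self.routes_before_pooling // self.pool_window
        total = self.routes_after_pooling
        for width in self.fc_widths:
            total *= width
        self.total = total


def count_paths_paper_lenet5(
        fc_widths: tuple[int, ...] = (120, 84)) -> PaperLeNetRouteCount:
    """Reproduce the closed-form LeNet-5 route count stepwise.

    Default widths give the canonical intermediate 100 and total 1,008,000.
    """
    return PaperLeNetRouteCount(fc_widths=tuple(fc_widths))
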