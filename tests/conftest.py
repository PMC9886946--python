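import numpy as np
import pytest

from treebp.architectures import Tree3Config, build_tree3, init_params


def toy_tree_config(seed: int = 0, activation: str = "relu") -> Tree3Config:
    """A small but structurally complete tree geometry (12x12 input)."""
    rng = np.random.default_rng(seed)
    return Tree3Config(
        channels=int(rng.integers(1, 3)),
        filters_per_channel=int(rng.integers(1, 3)),
        branches=int(rng.integers(1, 4)),
        height=12,
        width=12,
        slab_rows=int(rng.choice([1, 2, 4])),
        classes=int(rng.integers(2, 5)),
        activation=activation,
    )


def toy_tree_net(seed: int = 0, activation: str = "relu", batch: int = 3):
    """(spec, params, images, labels) for a random toy tree network."""
    cfg = toy_tree_config(seed, activation)
    spec = build_tree3(cfg)
    params = init_params(spec, seed + 1)
    rng = np.random.default_rng(seed + 2)
    x = rng.normal(0.0, 0.6, (batch, cfg.channels, 12, 12)).clip(-1, 1)
    y = rng.integers(0, cfg.classes, batch)
    return spec, params, x, y


@pytest.fixture
def small_tree():
    """Fixed (spec, params) pair: C=1, K=2, M=2 on a 12x12 input."""
    cfg = Tree3Config(channels=1, filters_per_channel=2, branches=2,
                      height=12, width=12, slab_rows=2, classes=3)
    spec = build_tree3(cfg)
    return spec, init_params(spec, 42)


def rel_diff(a: np.ndarray, b: np.ndarray) -> float:
    scale = max(np.abs(a).max(), np.abs(b).max(), 1e-30)
    return float(np.abs(a - b).max() / scale)
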