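"""Forward pass, backward engines, loss, optimizer and schedules."""

import numpy as np
import pytest

from conftest import rel_diff, toy_tree_net

from treebp.architectures import Tree3Config, build_tree3, init_params
from treebp.engine import (
    SCHEDULES,
    GradientSet,
    OptState,
    SingleRouteError,
    StaleTraceError,
    TrainingConfig,
    backward_pruned,
    backward_reference,
    forward,
    loss_cross_entropy,
    lr_schedule,
    sgd_step,
    weight_decay_at,
)


def scalar_chain_spec(classes=2):
    """1-pixel, 1-filter chain: conv(1x1) -> pool(1x1) -> tree(1 unit) -> FC."""
    cfg = Tree3Config(channels=1, filters_per_channel=1, branches=1,
                      height=1, width=1, filter_size=1, pool_size=1,
                      slab_rows=1, classes=classes)
    return build_tree3(cfg)


def set_weights(params, values):
    for i, v in values.items():
        params.weights[i][...] = v
    return params


class TestForward:
    def test_all_zero_input_gives_uniform_softmax(self, small_tree):
        spec, params = small_tree
        trace = forward(spec, params, np.zeros((2, 1, 12, 12)))
        for i in (0, 2):   # hidden layers
            assert (trace.post[i] == 0.0).all()
        assert np.allclose(trace.probs, 0.1 * 0 + 1.0 / 3)

    def test_softmax_normalized_and_pool_index_in_window(self):
        spec, params, x, _ = toy_tree_net(3)
        trace = forward(spec, params, x)
        assert np.allclose(trace.probs.sum(axis=1), 1.0, atol=1e-9)
        p = spec.layers[1].size
        idx = trace.pool_argmax[1]
        assert idx.min() >= 0 and idx.max() < p * p

    def test_identity_chain_passes_scalar_through(self):
        spec = scalar_chain_spec()
        params = set_weights(init_params(spec, 0), {0: 1.0, 2: 1.0, 3: 1.0})
        for x in (0.7, 2.5):
            trace = forward(spec, params, np.full((1, 1, 1, 1), x))
            assert np.allclose(trace.logits[0], [x, x])

    def test_tree_layer_matches_loop_oracle(self):
        """Tree pre-activation equals the hand-looped depth-and-slab sum."""
        spec, params, x, _ = toy_tree_net(11)
        tree = spec.layers[2]
        trace = forward(spec, params, x)
        pooled = trace.post[1]
        c, k, m = tree.channels, tree.depth, tree.branches
        j, r, sw = tree.slabs, tree.slab_rows, tree.in_w
        w = params.weights[2].reshape(c, k, m, tree.in_h, sw)
        for b in range(x.shape[0]):
            pb = pooled[b].reshape(c, k, tree.in_h, sw)
            for mi in range(m):
                for ci in range(c):
                    for ji in range(j):
                        acc = 0.0
                        for ki in range(k):
                            for row in range(ji * r, (ji + 1) * r):
                                for col in range(sw):
                                    acc += w[ci, ki, mi, row, col] * pb[ci, ki, row, col]
                        u = mi * (c * j) + ci * j + ji
                        assert trace.pre[2][b, u] == pytest.approx(acc, rel=1e-12)

    def test_batch_shape_mismatch_rejected(self, small_tree):
        spec, params = small_tree
        from treebp.architectures import ConfigurationError
        with pytest.raises(ConfigurationError, match="input"):
            forward(spec, params, np.zeros((2, 1, 10, 10)))

    def test_deterministic(self, small_tree):
        spec, params = small_tree
        x = np.random.default_rng(0).normal(size=(2, 1, 12, 12))
        a, b = forward(spec, params, x), forward(spec, params, x)
        assert (a.logits == b.logits).all()


class TestBackwardReference:
    def test_matches_central_finite_differences(self):
        spec, params, x, y = toy_tree_net(5)
        trace = forward(spec, params, x)
        grads = backward_reference(spec, params, trace, y)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for i, w in params.weights.items():
            for _ in range(15):
                idx = tuple(rng.integers(0, s) for s in w.shape)
                orig = w[idx]
                w[idx] = orig + eps
                lp = loss_cross_entropy(forward(spec, params, x), y).value
                w[idx] = orig - eps
                lm = loss_cross_entropy(forward(spec, params, x), y).value
                w[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads.grads[i][idx]) <= 1e-5 * (1 + abs(fd))

    def test_fc_gradient_is_outer_product_of_activity_and_error(self):
        """The readout gradient equals tree output (x) (probs - onehot) / B."""
        spec, params, x, y = toy_tree_net(6)
        trace = forward(spec, params, x)
        grads = backward_reference(spec, params, trace, y)
        err = loss_cross_entropy(trace, y).error / x.shape[0]
        expected = trace.post[2].T @ err
        assert np.allclose(grads.grads[3], expected, atol=1e-14)

    def test_batch_gradient_is_mean_of_per_sample_gradients(self):
        spec, params, x, y = toy_tree_net(7, batch=4)
        full = backward_reference(spec, params, forward(spec, params, x), y)
        singles = [
            backward_reference(spec, params, forward(spec, params, x[b:b + 1]),
                               y[b:b + 1])
            for b in range(4)
        ]
        for i in full.grads:
            mean = np.mean([s.grads[i] for s in singles], axis=0)
            assert np.allclose(full.grads[i], mean, atol=1e-14)

    def test_duplicated_sample_keeps_mean_gradient(self):
        spec, params, x, y = toy_tree_net(8, batch=1)
        g1 = backward_reference(spec, params, forward(spec, params, x), y)
        xx, yy = np.concatenate([x, x]), np.concatenate([y, y])
        g2 = backward_reference(spec, params, forward(spec, params, xx), yy)
        for i in g1.grads:
            assert np.allclose(g1.grads[i], g2.grads[i], atol=1e-14)

    def test_stale_trace_rejected(self, small_tree):
        spec, params = small_tree
        x = np.zeros((1, 1, 12, 12))
        trace = forward(spec, params, x)
        params.weights[0] += 1.0
        with pytest.raises(StaleTraceError):
            backward_reference(spec, params, trace, np.array([0]))


class TestBackwardPruned:
    @pytest.mark.parametrize("activation", ["relu", "sigmoid"])
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_reference(self, activation, seed):
        spec, params, x, y = toy_tree_net(seed, activation=activation)
        trace = forward(spec, params, x)
        ref = backward_reference(spec, params, trace, y)
        pruned = backward_pruned(spec, params, trace, y)
        assert set(ref.grads) == set(pruned.grads)
        for i in ref.grads:
            assert rel_diff(ref.grads[i], pruned.grads[i]) <= 1e-9

    def test_scalar_route_is_direct_product(self):
        """On a 1-unit chain, d(W_conv) = input * W_tree * sum_o W_fc[o] err[o]."""
        spec = scalar_chain_spec()
        params = set_weights(init_params(spec, 0), {0: 1.0, 2: 0.5})
        params.weights[3][...] = np.array([[0.3, -0.2]])
        x_val = 2.0
        trace = forward(spec, params, np.full((1, 1, 1, 1), x_val))
        y = np.array([0])
        err = trace.probs[0] - np.array([1.0, 0.0])
        grads = backward_pruned(spec, params, trace, y)
        expected = x_val * 0.5 * (np.array([0.3, -0.2]) @ err)
        assert grads.grads[0][0, 0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_inactive_relu_route_contributes_exactly_zero(self):
        spec = scalar_chain_spec()
        params = set_weights(init_params(spec, 0), {0: 1.0, 2: 0.5, 3: 0.3})
        trace = forward(spec, params, np.full((1, 1, 1, 1), -1.5))
        grads = backward_pruned(spec, params, trace, np.array([0]))
        assert grads.grads[0][0, 0, 0, 0] == 0.0      # conv pre-activation < 0
        assert grads.grads[2][0, 0, 0, 0] == 0.0      # pooled input is 0 too

    def test_skipped_contributions_are_zero_in_reference(self):
        """Pruning soundness: wherever pruned wrote nothing, reference has 0."""
        spec, params, x, y = toy_tree_net(13)
        trace = forward(spec, params, x)
        ref = backward_reference(spec, params, trace, y)
        pruned = backward_pruned(spec, params, trace, y)
        for i in ref.grads:
            untouched = pruned.grads[i] == 0.0
            assert np.allclose(ref.grads[i][untouched], 0.0, atol=1e-12)

    def test_non_tree_architecture_rejected(self):
        from treebp.architectures import build_lenet5
        spec = build_lenet5()
        params = init_params(spec, 0)
        trace = forward(spec, params, np.zeros((1, 3, 32, 32)))
        with pytest.raises(SingleRouteError, match="route"):
            backward_pruned(spec, params, trace, np.array([0]))


class TestLoss:
    def test_uniform_probabilities_give_log_classes(self):
        cfg = Tree3Config(channels=1, filters_per_channel=1, branches=1,
                          height=12, width=12, slab_rows=4, classes=10)
        spec = build_tree3(cfg)
        params = init_params(spec, 0)
        trace = forward(spec, params, np.zeros((3, 1, 12, 12)))
        report = loss_cross_entropy(trace, np.array([0, 5, 9]))
        assert report.value == pytest.approx(np.log(10), rel=1e-12)

    def test_certain_prediction_gives_zero_loss(self, small_tree):
        spec, params = small_tree
        trace = forward(spec, params, np.zeros((1, 1, 12, 12)))
        trace.logits = np.array([[80.0, 0.0, 0.0]])
        from treebp.engine import _softmax
        trace.probs = _softmax(trace.logits)
        assert loss_cross_entropy(trace, np.array([0])).value < 1e-12

    def test_error_vector_is_softmax_minus_onehot_by_finite_differences(self):
        logits = np.array([[0.3, -1.2, 0.8, 0.1]])
        target = np.array([2])

        def ce(z):
            zz = z - z.max()
            return float(-(zz[target[0]] - np.log(np.exp(zz).sum())))

        spec_probs = np.exp(logits[0] - logits[0].max())
        spec_probs /= spec_probs.sum()
        expected = spec_probs - np.array([0, 0, 1, 0])
        eps = 1e-7
        for o in range(4):
            z = logits[0].copy()
            z[o] += eps
            lp = ce(z)
            z[o] -= 2 * eps
            lm = ce(z)
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(expected[o], abs=1e-8)

    def test_target_out_of_range_rejected(self, small_tree):
        from treebp.architectures import ConfigurationError
        spec, params = small_tree
        trace = forward(spec, params, np.zeros((1, 1, 12, 12)))
        with pytest.raises(ConfigurationError, match="range"):
            loss_cross_entropy(trace, np.array([3]))


class TestOptimizer:
    def _grad_like(self, params, value):
        return GradientSet({i: np.full_like(w, value)
                            for i, w in params.weights.items()})

    def test_plain_gradient_descent_when_momentum_zero(self, small_tree):
        spec, params = small_tree
        before = params.copy()
        cfg = TrainingConfig(lr=0.1, momentum=0.0, weight_decay=0.0)
        sgd_step(params, self._grad_like(params, 0.5), cfg)
        for i in params.weights:
            assert np.allclose(params.weights[i],
                               before.weights[i] - 0.1 * 0.5, atol=1e-15)

    def test_zero_gradient_leaves_params_unchanged(self, small_tree):
        spec, params = small_tree
        before = params.copy()
        cfg = TrainingConfig(lr=0.1, momentum=0.9, weight_decay=0.0)
        sgd_step(params, self._grad_like(params, 0.0), cfg)
        for i in params.weights:
            assert (params.weights[i] == before.weights[i]).all()

    def test_two_step_nesterov_unroll(self):
        """w0=1, g=0.1, eta=0.1, mu=0.9:
        step 1: v=0.1,  w = 1 - 0.1*(0.1 + 0.9*0.1)   = 0.981
        step 2: v=0.19, w = 0.981 - 0.1*(0.1 + 0.9*0.19) = 0.9539
        """
        from treebp.architectures import ArchitectureSpec, FCLayer, NetworkParams
        spec = ArchitectureSpec(input_shape=(1, 1, 1), layers=(FCLayer(1, 1),))
        params = NetworkParams({0: np.array([[1.0]])}, seed=0)
        g = GradientSet({0: np.array([[0.1]])})
        cfg = TrainingConfig(lr=0.1, momentum=0.9, weight_decay=0.0)
        state = OptState()
        params, state = sgd_step(params, g, cfg, state)
        assert params.weights[0][0, 0] == pytest.approx(0.981, abs=1e-15)
        params, state = sgd_step(params, g, cfg, state)
        assert params.weights[0][0, 0] == pytest.approx(0.9539, abs=1e-15)

    def test_weight_decay_added_to_gradient(self):
        from treebp.architectures import ArchitectureSpec, FCLayer, NetworkParams
        spec = ArchitectureSpec(input_shape=(1, 1, 1), layers=(FCLayer(1, 1),))
        params = NetworkParams({0: np.array([[2.0]])}, seed=0)
        g = GradientSet({0: np.array([[0.0]])})
        cfg = TrainingConfig(lr=0.1, momentum=0.0, weight_decay=0.01)
        sgd_step(params, g, cfg)
        assert params.weights[0][0, 0] == pytest.approx(2.0 - 0.1 * 0.02)


class TestSchedules:
    def test_multiplicative_decay(self):
        cfg = TrainingConfig(lr=0.05, schedule=("multiplicative", 0.6, 20))
        assert lr_schedule(cfg, 0) == pytest.approx(0.05)
        assert lr_schedule(cfg, 40) == pytest.approx(0.05 * 0.6 ** 2)
        assert lr_schedule(cfg, 19) == pytest.approx(0.05)

    def test_piecewise_lenet_schedule(self):
        cfg = TrainingConfig(lr=0.01, schedule=SCHEDULES["lenet5_offline"])
        assert lr_schedule(cfg, 0) == 0.01
        assert lr_schedule(cfg, 120) == 0.005
        assert lr_schedule(cfg, 150) == 0.001
        assert lr_schedule(cfg, 999) == 0.001      # beyond range -> last value

    def test_multiplicative_schedule_non_increasing(self):
        cfg = TrainingConfig(lr=0.075, schedule=("multiplicative", 0.6, 20))
        etas = [lr_schedule(cfg, e) for e in range(0, 200)]
        assert all(a >= b for a, b in zip(etas, etas[1:]))

    def test_weight_decay_schedule(self):
        cfg = TrainingConfig(weight_decay=5e-5,
                             weight_decay_schedule=[(0, 5e-5), (50, 1e-5)])
        assert weight_decay_at(cfg, 10) == 5e-5
        assert weight_decay_at(cfg, 50) == 1e-5

    def test_invalid_hyperparameters_rejected(self):
        from treebp.architectures import ConfigurationError
        with pytest.raises(ConfigurationError):
            TrainingConfig(lr=0.0)
        with pytest.raises(ConfigurationError):
            TrainingConfig(momentum=1.0)
        with pytest.raises(ConfigurationError):
            TrainingConfig(weight_decay=-1e-5)
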