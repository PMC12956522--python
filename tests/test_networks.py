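"""Network construction, forward dynamics, surrogate-gradient training."""

import numpy as np
import pytest

from snnmanifold import (RESET, ArchitectureSpec, NeuronConfig,
                         TrainingConfig, add_recurrence, build_network,
                         evaluate, forward, predict, train)
from snnmanifold.networks import loss_and_grads

from _oracles import scalar_mlp_forward

BN_EPS_SCALE = 1.0 / np.sqrt(1.0 + 1e-5)  # identity-init BN rescale


def _toy_net(hidden=(3,), n_in=4, n_classes=2, seed=0, neuron=None):
    neuron = neuron or NeuronConfig(tau_m=2.0, v_th=1.0)
    spec = ArchitectureSpec(kind="mlp", input_shape=n_in,
                            hidden_sizes=hidden, n_classes=n_classes)
    return build_network(spec, neuron, seed=seed)


class TestBuild:
    def test_default_mlp_layer_shapes(self):
        net = build_network(ArchitectureSpec(), NeuronConfig(2.0, 1.0), seed=0)
        shapes = [blk.W.shape for blk in net.blocks]
        assert shapes == [(512, 784), (256, 512), (64, 256), (10, 64)]

    def test_default_conv_chain(self):
        spec = ArchitectureSpec(kind="conv", input_shape=(2, 12, 12))
        net = build_network(spec, NeuronConfig(2.0, 1.0), seed=0)
        names = [blk.name for blk in net.blocks]
        assert names == ["conv", "conv", "gap", "dense", "output"]
        assert net.blocks[0].W.shape == (64, 2, 3, 3)
        assert net.blocks[1].W.shape == (128, 64, 3, 3)
        assert net.blocks[3].W.shape == (64, 128)
        assert net.blocks[4].W.shape == (10, 64)

    def test_same_seed_same_weights(self):
        a = _toy_net(seed=9)
        b = _toy_net(seed=9)
        for key in a.parameters():
            np.testing.assert_array_equal(a.get_param(key), b.get_param(key))

    def test_shared_neuron_config_everywhere(self):
        neuron = NeuronConfig(tau_m=3.0, v_th=0.7)
        net = _toy_net(neuron=neuron)
        for blk in net.blocks:
            if getattr(blk, "spiking", False):
                assert blk.lif.neuron is neuron


class TestForward:
    def test_zero_input_zero_output_untrained(self):
        net = _toy_net()
        counts, _ = forward(net, np.zeros((10, 4)), policy=RESET)
        assert not counts.any()

    def test_matches_pen_and_paper_simulation(self):
        """Untrained net (identity BN) equals an all-scalar simulation."""
        net = _toy_net(hidden=(3, 2), n_in=4, n_classes=2, seed=3)
        rng = np.random.default_rng(0)
        x = (rng.random((6, 4)) < 0.5).astype(float)
        counts, _ = forward(net, x, policy=RESET)
        weights, biases = [], []
        for k, blk in enumerate(net.blocks):
            scale = BN_EPS_SCALE if blk.bn is not None else 1.0
            weights.append(blk.W * scale)
            biases.append(blk.b * scale)
        cfg = net.neuron
        expected = scalar_mlp_forward(weights, biases, x, cfg.alpha,
                                      cfg.v_th, cfg.v_reset)
        np.testing.assert_allclose(counts, expected, atol=1e-9)

    def test_reset_policy_erases_sample_history(self):
        net = _toy_net(seed=1)
        rng = np.random.default_rng(2)
        a = (rng.random((10, 4)) < 0.5).astype(float)
        b = (rng.random((10, 4)) < 0.5).astype(float)
        counts_b_alone, _ = forward(net, b, policy=RESET)
        forward(net, a, policy=RESET)
        counts_b_after_a, _ = forward(net, b, policy=RESET)
        np.testing.assert_array_equal(counts_b_alone, counts_b_after_a)

    def test_record_returns_binary_traces_for_all_spiking_layers(self):
        net = _toy_net(hidden=(3, 2))
        x = (np.random.default_rng(1).random((5, 4)) < 0.7).astype(float)
        _, rec = forward(net, x, record=True, true_label=0)
        assert len(rec.layer_spikes) == 3      # 2 hidden + output
        for trace in rec.layer_spikes:
            assert trace.shape[0] == 5
            assert set(np.unique(trace)).issubset({0, 1})


class TestPredict:
    def test_argmax_and_tie_rules(self):
        assert predict(np.array([0.1, 0.9, 0.3])) == 1
        assert predict(np.array([0.5, 0.5])) == 0
        assert predict(np.zeros(4)) == 0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            predict(np.array([]))

    def test_degenerate_sample_flagged_in_record(self):
        net = _toy_net()
        _, rec = forward(net, np.zeros((4, 4)), record=True)
        assert rec.degenerate


class TestTraining:
    def test_zero_epochs_leaves_network_unchanged(self):
        net = _toy_net(seed=4)
        before = {k: net.get_param(k).copy() for k in net.parameters()}
        x = np.zeros((8, 10, 4))
        train(net, x, np.zeros(8, dtype=int),
              TrainingConfig(T=10, epochs=0, seed=0))
        for key, value in before.items():
            np.testing.assert_array_equal(net.get_param(key), value)

    def test_same_seed_same_final_weights(self):
        rng = np.random.default_rng(5)
        x = (rng.random((40, 10, 4)) < 0.4).astype(np.int8)
        y = rng.integers(0, 2, 40)
        nets = []
        for _ in range(2):
            net = _toy_net(seed=6)
            train(net, x, y, TrainingConfig(T=10, epochs=3, seed=11))
            nets.append(net)
        for key in nets[0].parameters():
            np.testing.assert_array_equal(nets[0].get_param(key),
                                          nets[1].get_param(key))

    def test_horizon_mismatch_rejected(self):
        net = _toy_net()
        with pytest.raises(ValueError):
            train(net, np.zeros((4, 5, 4)), np.zeros(4, dtype=int),
                  TrainingConfig(T=10, epochs=1))

    def test_separable_task_reaches_95_percent(self, trained_mlp):
        """The default linearly separable task trains to >= 0.95 accuracy."""
        _, history = trained_mlp
        assert len(history) <= 20
        assert history.accuracy.iloc[-1] >= 0.95

    def test_surrogate_slope_changes_gradients_not_outputs(self):
        rng = np.random.default_rng(8)
        x = (rng.random((3, 10, 4)) < 0.5).astype(float)
        y = np.array([0, 1, 0])
        counts, grads = {}, {}
        for slope in (1.0, 5.0):
            net = _toy_net(seed=12)
            net.reset_state()
            _, g, c = loss_and_grads(net, x, y, slope=slope)
            counts[slope], grads[slope] = c, g
        np.testing.assert_array_equal(counts[1.0], counts[5.0])
        key = (0, "W")
        assert not np.allclose(grads[1.0][key], grads[5.0][key])

    def test_reset_evaluation_invariant_to_sample_order(self, trained_mlp,
                                                        encoded_splits,
                                                        default_dataset):
        net, _ = trained_mlp
        _, xte = encoded_splits
        y = default_dataset.test_y
        acc = evaluate(net, xte, y, policy=RESET)
        order = np.random.default_rng(3).permutation(len(y))
        acc_shuffled = evaluate(net, xte[order], y[order], policy=RESET)
        assert acc == acc_shuffled


class TestGradientCheck:
    def test_bptt_matches_finite_differences_of_smoothed_loss(self):
        """On a 3-neuron toy net, analytic BPTT gradients equal central
        finite differences of the surrogate-smoothed loss to 1e-4."""
        net = _toy_net(hidden=(3,), seed=0)
        add_recurrence(net, seed=1, init_std=0.1)
        rng = np.random.default_rng(2)
        x = (rng.random((2, 5, 4)) < 0.5).astype(float)
        y = np.array([0, 1])

        def smooth_loss():
            net.reset_state()
            loss, grads, _ = loss_and_grads(net, x, y, slope=2.0, smooth=True)
            return loss, grads

        _, grads = smooth_loss()
        eps = 1e-6
        checked = 0
        for key in net.parameters():
            param = net.get_param(key)
            grad = grads.get(key)
            if grad is None:
                continue
            flat_indices = np.unravel_index(
                np.linspace(0, param.size - 1, min(param.size, 6), dtype=int),
                param.shape)
            for idx in zip(*flat_indices):
                old = param[idx]
                param[idx] = old + eps
                lp, _ = smooth_loss()
                param[idx] = old - eps
                lm, _ = smooth_loss()
                param[idx] = old
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-7 or abs(grad[idx]) > 1e-7:
                    rel = abs(fd - grad[idx]) / max(abs(fd), abs(grad[idx]))
                    assert rel < 1e-4, f"{key}{idx}: fd={fd} an={grad[idx]}"
                    checked += 1
        assert checked > 10


class TestRecurrence:
    def test_zero_recurrence_is_identity(self):
        rng = np.random.default_rng(3)
        x = (rng.random((8, 4)) < 0.5).astype(float)
        base = _toy_net(hidden=(3,), seed=7)
        counts_base, _ = forward(base, x)
        rec = _toy_net(hidden=(3,), seed=7)
        add_recurrence(rec, seed=0)
        rec.blocks[0].Wrec[:] = 0.0
        counts_rec, _ = forward(rec, x)
        np.testing.assert_array_equal(counts_base, counts_rec)

    def test_matches_scalar_oracle_with_recurrence(self):
        """2-neuron recurrent hidden layer equals the brute-force loop."""
        net = _toy_net(hidden=(2,), n_in=3, seed=5)
        add_recurrence(net, seed=2, init_std=0.0)
        net.blocks[0].Wrec = np.array([[0.0, 2.0], [2.0, 0.0]])
        rng = np.random.default_rng(4)
        x = (rng.random((7, 3)) < 0.6).astype(float)
        counts, _ = forward(net, x)
        weights, biases = [], []
        for blk in net.blocks:
            scale = BN_EPS_SCALE if blk.bn is not None else 1.0
            weights.append(blk.W * scale)
            biases.append(blk.b * scale)
        cfg = net.neuron
        expected = scalar_mlp_forward(weights, biases, x, cfg.alpha, cfg.v_th,
                                      cfg.v_reset, wrec=net.blocks[0].Wrec,
                                      wrec_layer=0)
        np.testing.assert_allclose(counts, expected, atol=1e-9)

    def test_requires_hidden_layer(self):
        spec = ArchitectureSpec(kind="mlp", input_shape=4, hidden_sizes=(),
                                n_classes=2)
        net = build_network(spec, NeuronConfig(2.0, 1.0), seed=0)
        with pytest.raises(ValueError):
            add_recurrence(net)
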