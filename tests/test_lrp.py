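"""z-rule relevance propagation, smoothing and the contribution tables."""

import numpy as np
import pytest

from felanding.dnn import NetworkConfig, TrainedNetwork, initialize_network, scaled_down_config
from felanding.exceptions import ConfigurationError, SignalError
from felanding.lrp import (SMOOTH_KERNEL, aggregate, propagate, relevance_batch,
                           rescale_and_rank, smooth, trajectory_contributions)


def make_net(sizes, weights=None, biases=None, seed=0):
    cfg = NetworkConfig(n_inputs=sizes[0], hidden_layers=len(sizes) - 2,
                        hidden_units=sizes[1], n_outputs=sizes[-1], init_seed=seed)
    if weights is None:
        weights, biases = initialize_network(cfg)
    if biases is None:
        biases = [np.zeros(s) for s in sizes[1:]]
    return TrainedNetwork(config=cfg, weights=weights, biases=biases,
                          x_mean=np.zeros(sizes[0]), x_sd=np.ones(sizes[0]))


class TestPropagate:
    def test_single_linear_layer_decomposes_to_preactivations(self):
        # one linear map straight to the output: R_i = z_ij = u_i * w_ij
        w = np.array([[0.5], [-1.5], [2.0]])
        cfg = NetworkConfig(n_inputs=3, hidden_layers=1, hidden_units=1, n_outputs=1)
        # single weight layer only: hidden layer of size 1 with identity top
        net = make_net([3, 1, 1], weights=[w, np.array([[1.0]])],
                       biases=[np.zeros(1), np.zeros(1)])
        x = np.array([2.0, 1.0, 0.5])
        R = propagate(net, x, target=0)
        # relevance through the 1-unit bottleneck keeps the z_ij proportions
        zij = x * w[:, 0]
        np.testing.assert_allclose(R / R.sum(), zij / zij.sum(), atol=1e-9)

    def test_hand_worked_bias_free_two_layer(self):
        # 2 -> 2 -> 1 bias-free net, z-rule worked by hand
        w1 = np.array([[1.0, -0.5], [0.5, 1.0]])
        w2 = np.array([[2.0], [-1.0]])
        net = make_net([2, 2, 1], weights=[w1, w2])
        x = np.array([1.0, 2.0])
        u1 = np.tanh(x @ w1)
        z_out = u1 @ w2
        R_hand_hidden = u1 * w2[:, 0]  # z_ij for the top layer, R_out = z_out
        z1 = x @ w1
        R_hand_input = np.zeros(2)
        for j in range(2):
            for i in range(2):
                R_hand_input[i] += (x[i] * w1[i, j] / z1[j]) * R_hand_hidden[j]
        R = propagate(net, x, target=0)
        np.testing.assert_allclose(R, R_hand_input, rtol=1e-6)
        assert R.sum() == pytest.approx(z_out[0], rel=1e-6)

    def test_bias_free_conservation_to_output_score(self, rng):
        for seed in range(5):
            net = make_net([8, 6, 6, 2], seed=seed)
            net.biases = [np.zeros_like(b) for b in net.biases]
            x = rng.normal(size=8)
            scores, _ = net.forward(x, cache=True)
            target = int(np.argmax(scores[0]))
            R = propagate(net, x, target=target)
            assert R.sum() == pytest.approx(scores[0, target], rel=1e-6)

    def test_bias_absorption_matches_eq_multiplier_on_toy_net(self):
        # one layer with bias: the layer keeps R_out * (1 - b/z)
        w = np.array([[1.0], [2.0]])
        b = np.array([0.5])
        net = make_net([2, 1, 1], weights=[w, np.array([[1.0]])],
                       biases=[b, np.zeros(1)])
        x = np.array([1.0, 1.0])
        z = x @ w + b  # 3.5
        R = propagate(net, x, target=0)
        R_out = np.tanh(z) @ np.array([[1.0]])
        # relevance reaching the inputs lost the bias share of the first layer
        assert R.sum() == pytest.approx(float(R_out[0]) * (1 - b[0] / z[0]), rel=1e-6)

    def test_redistribute_mode_restores_conservation(self):
        w = np.array([[1.0], [2.0]])
        b = np.array([0.5])
        net = make_net([2, 1, 1], weights=[w, np.array([[1.0]])],
                       biases=[b, np.zeros(1)])
        x = np.array([1.0, 1.0])
        R = propagate(net, x, target=0, bias_mode="redistribute")
        R_out = float(np.tanh(x @ w + b) @ np.array([1.0]))
        assert R.sum() == pytest.approx(R_out, rel=1e-6)

    def test_zero_preactivation_stabilized(self):
        w = np.array([[1.0], [-1.0]])  # z_j = 0 for x = (1, 1)
        net = make_net([2, 1, 1], weights=[w, np.array([[1.0]])])
        R = propagate(net, np.ones(2), target=0)
        assert np.all(np.isfinite(R))


class TestAggregate:
    def test_single_correct_trial(self):
        maps = np.array([[1.0, -2.0, 0.5]])
        agg = aggregate(maps, np.array([True]))
        np.testing.assert_allclose(agg, [0.5, 1.0, 0.25])

    def test_sign_cancellation_avoided(self):
        v = np.array([1.0, -3.0, 2.0])
        agg = aggregate(np.vstack([v, -v]), np.array([True, True]))
        np.testing.assert_allclose(agg, np.abs(v) / 3.0)

    def test_masked_mean_matches_bruteforce(self, rng):
        maps = rng.normal(size=(12, 30))
        mask = rng.random(12) > 0.4
        agg = aggregate(maps, mask)
        brute = np.abs(maps[mask]).mean(axis=0)
        np.testing.assert_allclose(agg, brute / brute.max())

    def test_no_correct_trials_raises(self, rng):
        with pytest.raises(SignalError):
            aggregate(rng.normal(size=(3, 5)), np.zeros(3, bool))


class TestSmooth:
    def test_constant_blocks_invariant(self):
        v = np.concatenate([np.full(100, c) for c in (1.0, 5.0, -2.0, 0.0, 3.0, 7.0)])
        np.testing.assert_allclose(smooth(v), v, atol=1e-12)

    def test_single_pass_spike_kernel(self):
        v = np.zeros(600)
        v[50] = 1.0
        out = smooth(v, passes=1)
        np.testing.assert_allclose(out[49:52], SMOOTH_KERNEL)
        assert out[48] == 0 and out[52] == 0

    def test_triple_pass_equals_convolution_oracle(self):
        v = np.zeros(600)
        v[250] = 1.0  # interior of block 3
        out = smooth(v, passes=3)
        kernel = np.array(SMOOTH_KERNEL)
        triple = np.convolve(np.convolve(kernel, kernel), kernel)  # 7 taps
        np.testing.assert_allclose(out[247:254], triple, atol=1e-12)

    def test_block_totals_preserved_and_no_bleed(self, rng):
        v = np.abs(rng.normal(size=600))
        out = smooth(v)
        for b in range(6):
            sl = slice(b * 100, (b + 1) * 100)
            assert out[sl].sum() == pytest.approx(v[sl].sum(), rel=1e-12)
        spike = np.zeros(600)
        spike[99] = 1.0  # boundary of block 1
        np.testing.assert_array_equal(smooth(spike)[100:], 0.0)

    def test_wrong_length_raises(self):
        with pytest.raises(ConfigurationError):
            smooth(np.zeros(123))


class TestRescaleAndRank:
    def test_max_exactly_one(self, rng):
        v = np.abs(rng.normal(size=600)) + 0.1
        rescaled, _ = rescale_and_rank(v)
        assert rescaled.max() == 1.0 and rescaled.min() == 0.0

    def test_strictly_decreasing_vector_masks_prefix(self):
        v = np.linspace(10, 1, 600)
        _, mask = rescale_and_rank(v, k=100)
        np.testing.assert_array_equal(np.nonzero(mask)[0], np.arange(100))

    def test_matches_sort_oracle(self, rng):
        v = rng.random(600)
        _, mask = rescale_and_rank(v, k=100)
        oracle = set(sorted(range(600), key=lambda i: (-v[i], i))[:100])
        assert set(np.nonzero(mask)[0]) == oracle

    def test_ties_break_to_lower_index(self):
        v = np.zeros(600)
        v[10] = v[20] = v[30] = 1.0
        v[5] = 0.5
        _, mask = rescale_and_rank(v, k=2)
        assert set(np.nonzero(mask)[0]) == {10, 20}

    def test_all_zero_raises(self):
        with pytest.raises(SignalError):
            rescale_and_rank(np.zeros(600))


class TestTrajectoryContributions:
    def test_uniform_vector_equal_sixths(self):
        pct, joints = trajectory_contributions(np.ones(600))
        for v in pct.values():
            assert v == pytest.approx(100 / 6)
        for v in joints.values():
            assert v == pytest.approx(100 / 3)

    def test_block_percentages_reproduce_published_joint_totals(self):
        """Six per-trajectory percentages summing as wrist 41.23, elbow 33.88,
        shoulder 24.90 (the distal-dominant low-height pair)."""
        shares = (19.98, 16.81, 11.06, 21.25, 17.07, 13.84)
        v = np.concatenate([np.full(100, s / 100) for s in shares])
        pct, joints = trajectory_contributions(v)
        # the reference percentages themselves carry two-decimal rounding (they
        # total 100.01), so agreement is to the printed precision
        for name, s in zip(pct, shares):
            assert pct[name] == pytest.approx(s, abs=0.01)
        assert joints["wrist"] == pytest.approx(41.23, abs=0.01)
        assert joints["elbow"] == pytest.approx(33.88, abs=0.01)
        assert joints["shoulder"] == pytest.approx(24.90, abs=0.01)
        # joint totals are exactly the sums of their two block shares
        assert joints["wrist"] == pytest.approx(pct["wrist_angle"] + pct["wrist_moment"])

    def test_matches_block_sum_oracle_and_sums_to_100(self, rng):
        v = np.abs(rng.normal(size=600))
        pct, joints = trajectory_contributions(v)
        brute = [100 * v[b * 100:(b + 1) * 100].sum() / v.sum() for b in range(6)]
        np.testing.assert_allclose(list(pct.values()), brute, atol=1e-9)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(joints.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_raises(self):
        with pytest.raises(SignalError):
            trajectory_contributions(np.zeros(600))


class TestBatch:
    def test_relevance_batch_matches_per_row(self, rng):
        net = make_net([10, 6, 6, 2], seed=4)
        X = rng.normal(size=(4, 10))
        maps = relevance_batch(net, X)
        for i in range(4):
            np.testing.assert_allclose(maps[i], propagate(net, X[i]), atol=1e-12)
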