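"""Attention modules, residual blocks and the assembled classifier."""

import numpy as np
import pytest

from hepatoscope.nn import (
    AttentionResNet,
    ChannelAttention,
    NetworkConfig,
    ResidualBlock,
    SpatialAttention,
    Tensor,
    build_model,
)

RNG = np.random.default_rng(99)


class TestChannelAttention:
    def test_weights_strictly_inside_unit_interval(self):
        mod = ChannelAttention(4, 2, np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((3, 4, 5, 6)))
        w = mod.gate(x).data
        assert w.shape == (3, 4)
        assert np.all((w > 0) & (w < 1))

    def test_zero_input_gives_half_gates(self):
        # biases are zero-initialised, so a zero input maps to sigmoid(0)
        mod = ChannelAttention(4, 2, np.random.default_rng(0))
        w = mod.gate(Tensor(np.zeros((2, 4, 3, 3)))).data
        np.testing.assert_allclose(w, 0.5)

    def test_hand_set_weights_reproduce_hand_computation(self):
        mod = ChannelAttention(2, 2, np.random.default_rng(0))
        mod.fc1.weight.data = np.array([[1.0], [-1.0]])  # (C=2, hidden=1)
        mod.fc1.bias.data = np.array([0.0])
        mod.fc2.weight.data = np.array([[2.0, -1.0]])  # (hidden=1, C=2)
        mod.fc2.bias.data = np.array([0.0])
        x = np.zeros((1, 2, 2, 2))
        x[0, 0] = [[1.0, 2.0], [3.0, 4.0]]  # avg 2.5, max 4
        x[0, 1] = [[0.0, 0.0], [0.0, 8.0]]  # avg 2.0, max 8
        # avg path: hidden = relu(2.5 - 2.0) = 0.5 -> (1.0, -0.5)
        # max path: hidden = relu(4 - 8) = 0 -> (0, 0)
        expected = 1 / (1 + np.exp(-np.array([1.0, -0.5])))
        got = mod.gate(Tensor(x)).data[0]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_reduction_ratio_must_divide_channels(self):
        with pytest.raises(ValueError):
            ChannelAttention(4, 3, np.random.default_rng(0))


class TestSpatialAttention:
    def test_map_shape_and_range(self):
        mod = SpatialAttention(7, np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((2, 4, 15, 30)))
        m = mod.gate(x).data
        assert m.shape == (2, 1, 15, 30)
        assert np.all((m > 0) & (m < 1))

    def test_zero_input_gives_uniform_half_map(self):
        mod = SpatialAttention(5, np.random.default_rng(0))
        m = mod.gate(Tensor(np.zeros((1, 3, 8, 8)))).data
        np.testing.assert_allclose(m, 0.5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            SpatialAttention(4, np.random.default_rng(0))


class TestResidualBlock:
    def test_zeroed_branch_passes_input_through_relu(self):
        blk = ResidualBlock(3, 3, np.random.default_rng(0))
        for name in ("conv1", "conv2"):
            getattr(blk, name).weight.data[:] = 0.0
            getattr(blk, name).bias.data[:] = 0.0
        x = RNG.standard_normal((2, 3, 4, 5))
        out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)

    def test_spatial_shape_preserved(self):
        blk = ResidualBlock(2, 2, np.random.default_rng(1), use_attention=True, reduction_ratio=2)
        out = blk(Tensor(RNG.standard_normal((1, 2, 15, 30))))
        assert out.shape == (1, 2, 15, 30)

    def test_channel_change_uses_projection_shortcut(self):
        blk = ResidualBlock(2, 6, np.random.default_rng(2))
        assert blk.shortcut is not None
        out = blk(Tensor(RNG.standard_normal((1, 2, 6, 6))))
        assert out.shape == (1, 6, 6, 6)

    def test_gradient_flows_through_shortcut_when_branch_frozen(self):
        blk = ResidualBlock(1, 1, np.random.default_rng(3))
        for name in ("conv1", "conv2"):
            conv = getattr(blk, name)
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
        x = np.abs(RNG.standard_normal((1, 1, 3, 3))) + 0.1  # positive: relu transparent
        t = Tensor(x, requires_grad=True)
        blk(t).sum().backward()
        np.testing.assert_allclose(t.grad, np.ones_like(x), atol=1e-12)


class TestBuildModel:
    def test_same_seed_same_initial_predictions(self):
        cfg = NetworkConfig(stem_channels=4, n_blocks=1, reduction_ratio=2, init_seed=11)
        x = RNG.standard_normal((3, 15, 30))
        p1 = build_model(cfg).predict_proba(x)
        p2 = build_model(cfg).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_different_seed_different_predictions(self):
        base = dict(stem_channels=4, n_blocks=1, reduction_ratio=2)
        x = RNG.standard_normal((3, 15, 30))
        p1 = build_model(NetworkConfig(**base, init_seed=1)).predict_proba(x)
        p2 = build_model(NetworkConfig(**base, init_seed=2)).predict_proba(x)
        assert not np.array_equal(p1, p2)

    def test_probabilities_sum_to_one(self):
        model = build_model(NetworkConfig(stem_channels=4, n_blocks=1, reduction_ratio=2))
        p = model.predict_proba(RNG.standard_normal((5, 15, 30)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_attention_adds_parameters(self):
        base = dict(stem_channels=8, n_blocks=2, reduction_ratio=4)
        with_att = build_model(NetworkConfig(**base, use_attention=True)).n_parameters()
        without = build_model(NetworkConfig(**base, use_attention=False)).n_parameters()
        assert with_att > without

    def test_batch_independence_and_permutation_equivariance(self):
        model = build_model(NetworkConfig(stem_channels=4, n_blocks=1, reduction_ratio=2))
        x = RNG.standard_normal((6, 15, 30))
        full = model.predict_proba(x)
        single = model.predict_proba(x[2:3])
        np.testing.assert_allclose(full[2], single[0], atol=1e-12)
        perm = RNG.permutation(6)
        np.testing.assert_allclose(model.predict_proba(x[perm]), full[perm], atol=1e-12)

    def test_wrong_input_shape_rejected(self):
        model = build_model(NetworkConfig(stem_channels=4, n_blocks=1, reduction_ratio=2))
        with pytest.raises(ValueError):
            model.forward(Tensor(np.zeros((1, 1, 10, 10))))

    @pytest.mark.parametrize(
        "bad",
        [dict(spatial_kernel=4), dict(reduction_ratio=5), dict(n_classes=3), dict(n_blocks=0)],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            NetworkConfig(**bad)
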