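"""Convolutional classifier tests: Table-style shape chain, CBAM gates
against hand/loop oracles, the square→pool→log head, and parameter budgets."""

import numpy as np
import pytest

from macnet import nn
from macnet.errors import ConfigurationError
from macnet.model import (
    CBAM,
    ChannelAttention,
    MACNet,
    ModelConfig,
    SpatialAttention,
    build_model,
    count_parameters,
    cross_entropy,
    softmax_probs,
)

RNG = np.random.default_rng(0)


def tensor(a):
    return nn.Tensor(np.asarray(a, dtype=np.float64))


class TestTemporalConv:
    def conv(self, weight_fn):
        cfg = ModelConfig(branch=0)
        model = build_model(cfg, seed=0, dtype=np.float64)
        weight_fn(model.temporal_conv)
        return model.temporal_conv

    def test_output_time_length_226(self):
        cfg = ModelConfig()
        model = build_model(cfg, seed=0)
        x = nn.Tensor(RNG.random((2, 1, 61, 250), dtype=np.float32))
        out = model.temporal_conv(x)
        assert out.shape == (2, 40, 61, 226)

    def test_impulse_kernel_is_identity_crop(self):
        conv = self.conv(lambda c: None)
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
        conv.weight.data[0, 0, 0, 0] = 1.0  # unit impulse at kernel start
        x = RNG.standard_normal((1, 1, 3, 250))
        out = conv(tensor(x)).data
        np.testing.assert_allclose(out[0, 0], x[0, 0, :, :226], atol=1e-12)

    def test_ones_kernel_equals_moving_sum(self):
        """All-ones filter on a ramp = 25-term moving sum via cumsum oracle."""
        conv = self.conv(lambda c: None)
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
        conv.weight.data[0, 0, 0, :] = 1.0
        ramp = np.arange(250, dtype=float)[None, None, None, :]
        out = conv(tensor(ramp)).data[0, 0, 0]
        csum = np.concatenate([[0.0], np.cumsum(ramp[0, 0, 0])])
        expected = csum[25:] - csum[:-25]
        np.testing.assert_allclose(out, expected, atol=1e-9)


class TestChannelAttention:
    def make(self, n_maps=2, ratio=1):
        return ChannelAttention(n_maps, ratio, rng=np.random.default_rng(1))

    def test_zero_mlp_gives_half(self):
        ca = self.make(4, 2)
        for p in ca.parameters():
            p.data[...] = 0.0
        f = tensor(RNG.standard_normal((3, 4, 5, 6)))
        np.testing.assert_allclose(ca(f).data, 0.5, atol=1e-12)

    def test_gate_strictly_inside_unit_interval(self):
        ca = self.make(8, 2)
        mc = ca(tensor(RNG.standard_normal((2, 8, 4, 4)))).data
        assert np.all(mc > 0) and np.all(mc < 1)

    def test_hand_arithmetic_oracle(self):
        """2 maps, 2×2 toy, hand-set weights; shared MLP over avg/max pooled
        descriptors, summed, sigmoid — atol 1e-8."""
        ca = self.make(2, 1)  # hidden width 2
        W0 = np.array([[0.5, -0.3], [0.2, 0.7]])   # [in, hidden]
        b0 = np.array([0.1, -0.2])
        W1 = np.array([[1.0, 0.4], [-0.6, 0.3]])   # [hidden, out]
        b1 = np.array([0.05, -0.1])
        ca.fc0.weight.data[...] = W0
        ca.fc0.bias.data[...] = b0
        ca.fc1.weight.data[...] = W1
        ca.fc1.bias.data[...] = b1
        f = np.array([[[[1.0, -2.0], [0.5, 3.0]],
                       [[0.0, 4.0], [-1.0, 2.0]]]])
        avg = f.mean(axis=(2, 3))[0]
        mx = f.max(axis=(2, 3))[0]

        def mlp(v):
            h = np.maximum(v @ W0 + b0, 0.0)
            return h @ W1 + b1

        expected = 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))
        np.testing.assert_allclose(ca(tensor(f)).data[0], expected, atol=1e-8)

    def test_zero_hidden_width_rejected(self):
        with pytest.raises(ConfigurationError, match="hidden"):
            ChannelAttention(4, 8)


class TestSpatialAttention:
    def make(self):
        return SpatialAttention(7, rng=np.random.default_rng(2))

    def test_zero_conv_gives_half(self):
        sa = self.make()
        sa.conv.weight.data[...] = 0.0
        sa.conv.bias.data[...] = 0.0
        f = tensor(RNG.standard_normal((2, 5, 9, 13)))
        out = sa(f).data
        assert out.shape == (2, 1, 9, 13)
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    @pytest.mark.parametrize("H,W", [(1, 7), (9, 13), (61, 226)])
    def test_same_padding_preserves_spatial_dims(self, H, W):
        sa = self.make()
        out = sa(tensor(RNG.standard_normal((1, 3, H, W)))).data
        assert out.shape == (1, 1, H, W)

    def test_loop_oracle_on_single_map(self):
        """Descriptors and the 7×7 conv evaluated with explicit loops."""
        sa = self.make()
        f = RNG.standard_normal((1, 3, 4, 5))
        w = sa.conv.weight.data
        b = float(sa.conv.bias.data[0])
        avg = f.mean(axis=1)[0]
        mx = f.max(axis=1)[0]
        stacked = np.stack([avg, mx])          # [2, H, W]
        padded = np.pad(stacked, ((0, 0), (3, 3), (3, 3)))
        H, W = 4, 5
        expected = np.zeros((H, W))
        for h in range(H):
            for x in range(W):
                acc = b
                for c in range(2):
                    for i in range(7):
                        for j in range(7):
                            acc += w[0, c, i, j] * padded[c, h + i, x + j]
                expected[h, x] = 1.0 / (1.0 + np.exp(-acc))
        np.testing.assert_allclose(sa(tensor(f)).data[0, 0], expected,
                                   atol=1e-8)


class TestCBAM:
    def make(self, n_maps=4, ratio=2):
        return CBAM(n_maps, ratio, 7, rng=np.random.default_rng(3))

    def test_saturated_gates_double_the_input(self):
        """Large positive biases force Mc ≡ Ms ≡ 1, so F + F″ → 2F."""
        cb = self.make()
        for p in cb.parameters():
            p.data[...] = 0.0
        cb.channel.fc1.bias.data[...] = 50.0
        cb.spatial.conv.bias.data[...] = 50.0
        f = RNG.standard_normal((2, 4, 3, 5))
        out = cb(tensor(f)).data
        np.testing.assert_allclose(out, 2.0 * f, atol=1e-6)

    def test_composition_matches_sequential_hand_evaluation(self):
        cb = self.make()
        f = RNG.standard_normal((2, 4, 3, 5))
        mc = cb.channel(tensor(f)).data
        f_prime = f * mc[:, :, None, None]
        ms = cb.spatial(tensor(f_prime)).data
        expected = f + ms * f_prime
        np.testing.assert_allclose(cb(tensor(f)).data, expected, atol=1e-8)

    def test_shape_preserved_at_model_geometry(self):
        cb = CBAM(40, 16, 7, rng=np.random.default_rng(4))
        for p in cb.parameters():
            p.data = p.data.astype(np.float32)
        f = nn.Tensor(RNG.random((1, 40, 61, 226), dtype=np.float32))
        assert cb(f).shape == (1, 40, 61, 226)

    def test_gates_never_vanish(self):
        cb = self.make()
        f = tensor(RNG.standard_normal((2, 4, 3, 5)))
        cb(f, keep_gates=True)
        assert np.all(cb.last_channel_gate > 0)
        assert np.all(cb.last_spatial_gate > 0)


class TestHead:
    def test_spatial_conv_head_shapes(self):
        model = build_model(ModelConfig(branch=0), seed=0)
        x = nn.Tensor(RNG.random((2, 40, 61, 226), dtype=np.float32))
        out = model.spatial_conv(x)
        assert out.shape == (2, 40, 1, 226)
        pooled = nn.avg_pool2d(out, (1, 75), (1, 15))
        assert pooled.shape == (2, 40, 1, 11)

    def test_safe_log_never_minus_inf(self):
        out = nn.safe_log(tensor([[1e-12, 0.0, 2.0]]), eps=1e-6).data
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out[0, :2], np.log(1e-6))

    def test_constant_map_pools_to_two_log_c(self):
        """Constant c, square on: pooled value c², safe-logged to 2·log|c|."""
        c = -1.7
        x = tensor(np.full((1, 1, 1, 226), c))
        pooled = nn.avg_pool2d(nn.square(x), (1, 75), (1, 15))
        out = nn.safe_log(pooled, eps=1e-6).data
        np.testing.assert_allclose(out, 2.0 * np.log(abs(c)), atol=1e-10)


class TestClassifier:
    def test_uniform_softmax_for_equal_logits(self):
        np.testing.assert_allclose(
            softmax_probs(np.array([2.0, 2.0, 2.0, 2.0])), 0.25, atol=1e-12
        )

    def test_shift_invariance(self):
        z = RNG.standard_normal(4)
        np.testing.assert_allclose(
            softmax_probs(z), softmax_probs(z + 13.7), atol=1e-12
        )

    def test_hand_cross_entropy(self):
        """logits (1,0,0,0), true class 0 → −log(e/(e+3)) ≈ 0.7437."""
        loss = cross_entropy(np.array([[1.0, 0.0, 0.0, 0.0]]), np.array([0]))
        expected = -np.log(np.e / (np.e + 3.0))
        assert loss == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.7437, abs=5e-5)

    def test_probabilities_sum_to_one_end_to_end(self):
        model = build_model(ModelConfig(), seed=1)
        p = model.predict_proba(RNG.random((3, 61, 250), dtype=np.float32))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)


class TestBuildModel:
    def test_branch2_forward_produces_4_logits(self):
        model = build_model(ModelConfig(branch=2), seed=0)
        x = nn.Tensor(RNG.random((2, 1, 61, 250), dtype=np.float32))
        assert model(x).shape == (2, 4)

    @pytest.mark.parametrize(
        "branch,expected",
        [(0, 100_444), (1, 111_607), (2, 111_908)],
    )
    def test_parameter_budgets(self, branch, expected):
        assert count_parameters(ModelConfig(branch=branch)) == expected

    def test_branch0_has_no_attention_modules(self):
        model = build_model(ModelConfig(branch=0), seed=0)
        assert model.temporal_attn is None and model.cbam is None
        model1 = build_model(ModelConfig(branch=1), seed=0)
        assert model1.temporal_attn is not None and model1.cbam is None

    @pytest.mark.parametrize(
        "tweaks",
        [{"use_temporal_conv": False}, {"use_spatial_conv": False}],
    )
    def test_module_removal_variants_run_end_to_end(self, tweaks):
        cfg = ModelConfig(branch=0, **tweaks)
        model = build_model(cfg, seed=0)
        x = nn.Tensor(RNG.random((2, 1, 61, 250), dtype=np.float32))
        assert model(x).shape == (2, 4)

    def test_invalid_branch_rejected(self):
        with pytest.raises(ConfigurationError, match="branch"):
            build_model(ModelConfig(branch=3), seed=0)

    def test_gradient_reaches_every_parameter(self):
        model = build_model(ModelConfig(branch=2), seed=2)
        model.train_mode()
        model.rng = np.random.default_rng(0)
        x = nn.Tensor(RNG.random((4, 1, 61, 250), dtype=np.float32))
        loss = nn.cross_entropy_with_logits(model(x), np.array([0, 1, 2, 3]))
        nn.backward(loss)
        for p in model.parameters():
            assert p.grad is not None and np.linalg.norm(p.grad) > 0

    def test_shape_chain_matches_published_architecture(self):
        """Every intermediate output shape for B=2, C=61, T=250."""
        cfg = ModelConfig(branch=2)
        model = build_model(cfg, seed=0)
        x = nn.Tensor(RNG.random((2, 1, 61, 250), dtype=np.float32))
        h = model.temporal_attn(x)
        assert h.shape == (2, 1, 61, 250)          # residual add
        h = model.temporal_conv(h)
        assert h.shape == (2, 40, 61, 226)         # temporal convolution
        h = model.cbam(h)
        assert h.shape == (2, 40, 61, 226)         # CBAM + skip
        h = model.spatial_conv(h)
        assert h.shape == (2, 40, 1, 226)          # spatial convolution
        h = model.bn(h, training=False)
        h = nn.avg_pool2d(nn.square(h), (1, 75), (1, 15))
        assert h.shape == (2, 40, 1, 11)           # average pooling
        logits = model.classifier(nn.safe_log(h, 1e-6))
        assert logits.shape == (2, 4, 1, 1)        # classifying convolution

    def test_attention_state_export(self):
        from macnet.model import attention_state

        model = build_model(ModelConfig(branch=2), seed=3)
        sample = RNG.random((61, 250)).astype(np.float32)
        state = attention_state(model, sample)
        assert state.temporal.shape == (250, 250)
        np.testing.assert_allclose(state.temporal.sum(axis=1), 1.0, atol=1e-5)
        assert state.channel_gate.shape == (40,)
        assert np.all((state.channel_gate > 0) & (state.channel_gate < 1))
        assert state.spatial_gate.shape == (1, 61, 226)

        branch0 = build_model(ModelConfig(branch=0), seed=3)
        state0 = attention_state(branch0, sample)
        assert state0.temporal is None and state0.channel_gate is None

    def test_shallow_backbone_matches_loop_oracle_at_reduced_dims(self):
        """Branch-0 forward (eval mode) ≡ an explicit per-layer loop
        computation at C=4, T=40."""
        cfg = ModelConfig(C=4, T=40, temporal_kernel=5, pool_kernel=9,
                          pool_stride=3, classifier_kernel=10, branch=0)
        assert cfg.pooled_len() == 10
        model = MACNet(cfg, rng=np.random.default_rng(9), dtype=np.float64)
        model.eval_mode()
        x = RNG.standard_normal((1, 1, 4, 40))
        logits = model(nn.Tensor(x)).data[0]

        # --- independent recomputation with plain loops/numpy ---
        w_t = model.temporal_conv.weight.data
        b_t = model.temporal_conv.bias.data
        t1 = 36
        conv1 = np.zeros((40, 4, t1))
        for f in range(40):
            for ch in range(4):
                for t in range(t1):
                    conv1[f, ch, t] = np.dot(w_t[f, 0, 0], x[0, 0, ch, t:t + 5]) + b_t[f]
        w_s = model.spatial_conv.weight.data
        b_s = model.spatial_conv.bias.data
        conv2 = np.zeros((40, 1, t1))
        for f in range(40):
            conv2[f, 0] = np.tensordot(w_s[f, :, :, 0], conv1, axes=2) + b_s[f]
        bn = (conv2 - model.bn.running_mean[:, None, None]) / np.sqrt(
            model.bn.running_var[:, None, None] + 1e-5
        )
        sq = bn ** 2
        pooled = np.stack(
            [sq[:, 0, i * 3:i * 3 + 9].mean(axis=1) for i in range(10)], axis=1
        )
        feats = np.log(np.maximum(pooled, 1e-6))
        w_c = model.classifier.weight.data
        b_c = model.classifier.bias.data
        expected = np.array(
            [np.tensordot(w_c[m, :, 0, :], feats, axes=2) + b_c[m]
             for m in range(4)]
        )
        np.testing.assert_allclose(logits, expected, atol=1e-8)
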