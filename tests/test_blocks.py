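"""Block-level value contracts against naive loop oracles."""

import numpy as np
import pytest

from _oracles import (conv2d_oracle, conv_block_oracle, fusion_oracle,
                      gap_oracle, max_pool_oracle, sa_oracle, se_oracle,
                      spp_oracle)
from gnet import blocks, nn
from gnet.blocks import (ConvParams, SEWeights, SPPParams, conv_block,
                         fusion_block, global_average_pool, max_pool,
                         sa_block, se_block, spp_block)
from gnet.exceptions import ConfigurationError, ShapeError


def random_image(rng, h=8, w=8, c=4):
    return rng.standard_normal((h, w, c)).astype(np.float32)


# --------------------------------------------------------------------------
# global average pooling
# --------------------------------------------------------------------------

class TestGlobalAveragePool:
    def test_tiny_example(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[..., None]
        assert global_average_pool(x) == pytest.approx([2.5])

    def test_constant_channel(self, rng):
        x = np.full((5, 7, 3), 0.0, dtype=np.float32)
        x[..., 0], x[..., 1], x[..., 2] = -1.5, 0.25, 42.0
        np.testing.assert_allclose(global_average_pool(x), [-1.5, 0.25, 42.0],
                                   atol=1e-6)

    def test_matches_double_loop(self, rng):
        x = random_image(rng, 8, 8, 4)
        np.testing.assert_allclose(global_average_pool(x), gap_oracle(x),
                                   atol=1e-7)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ShapeError):
            global_average_pool(np.zeros((0, 4, 2)))


# --------------------------------------------------------------------------
# squeeze-excitation
# --------------------------------------------------------------------------

class TestSEBlock:
    def test_zero_weights_halve_input(self, rng):
        x = random_image(rng, 4, 4, 6)
        w = SEWeights(w1=np.zeros((6, 2)), w2=np.zeros((2, 6)),
                      b1=np.zeros(2), b2=np.zeros(6))
        np.testing.assert_allclose(se_block(x, w), 0.5 * x, atol=1e-6)

    def test_zero_input_stays_zero(self, rng):
        w = SEWeights.random(channels=5, rng=rng)
        out = se_block(np.zeros((3, 3, 5), np.float32), w)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_straight_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = random_image(rng, 4, 4, 8)
        w = SEWeights(
            w1=rng.standard_normal((8, 3)).astype(np.float32),
            w2=rng.standard_normal((3, 8)).astype(np.float32),
            b1=rng.standard_normal(3).astype(np.float32),
            b2=rng.standard_normal(8).astype(np.float32),
        )
        expected, gate = se_oracle(x, w.w1, w.b1, w.w2, w.b2)
        np.testing.assert_allclose(se_block(x, w), expected, atol=1e-6)
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_gating_shrinks_magnitudes(self, rng):
        x = random_image(rng, 6, 6, 4)
        out = se_block(x, SEWeights.random(4, rng=rng))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            se_block(random_image(rng, 4, 4, 5), SEWeights.random(6, rng=rng))

    def test_layer_class_matches_functional(self, rng):
        x = random_image(rng, 5, 5, 8)
        layer = blocks.SEBlock(8, reduction=4, rng=rng)
        w = SEWeights(w1=layer.fc1.weight.data, b1=layer.fc1.bias.data,
                      w2=layer.fc2.weight.data, b2=layer.fc2.bias.data)
        out = layer(nn.Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, se_block(x, w), atol=1e-6)


# --------------------------------------------------------------------------
# self-attention
# --------------------------------------------------------------------------

class TestSABlock:
    def test_zero_kernel_gives_half_gate(self, rng):
        x = random_image(rng, 4, 4, 3)
        out, attn = sa_block(x, np.zeros((1, 1, 3, 3)), np.zeros(3))
        np.testing.assert_allclose(attn, 0.5, atol=1e-7)
        np.testing.assert_allclose(out, 0.5 * x, atol=1e-6)

    def test_zero_input(self, rng):
        w = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        out, _ = sa_block(np.zeros((3, 3, 4), np.float32), w)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_and_gating_bound(self, seed):
        rng = np.random.default_rng(seed)
        x = random_image(rng, 6, 6, 3)
        w = rng.standard_normal((1, 1, 3, 3)).astype(np.float32)
        b = rng.standard_normal(3).astype(np.float32)
        out, attn = sa_block(x, w, b)
        exp_out, exp_attn = sa_oracle(x, w, b)
        np.testing.assert_allclose(out, exp_out, atol=1e-6)
        np.testing.assert_allclose(attn, exp_attn, atol=1e-6)
        assert np.all((attn > 0) & (attn < 1))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_non_1x1_kernel_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sa_block(random_image(rng), rng.standard_normal((3, 3, 4, 4)))


# --------------------------------------------------------------------------
# max pooling
# --------------------------------------------------------------------------

class TestMaxPool:
    def test_four_by_four_example(self):
        x = np.arange(1, 17, dtype=np.float32).reshape(4, 4)[..., None]
        out = max_pool(x, 2)
        np.testing.assert_array_equal(out[..., 0], [[6, 8], [14, 16]])

    def test_constant_input_idempotent(self):
        x = np.full((8, 8, 2), 3.25, dtype=np.float32)
        for p in (1, 2, 4, 8):
            assert np.all(max_pool(x, p) == 3.25)

    def test_p_equals_one_is_identity(self, rng):
        x = random_image(rng)
        np.testing.assert_array_equal(max_pool(x, 1), x)

    @pytest.mark.parametrize("p", [2, 3])
    def test_matches_window_loop(self, rng, p):
        x = random_image(rng, 7, 8, 3)
        np.testing.assert_allclose(max_pool(x, p),
                                   max_pool_oracle(x, p), atol=0)

    def test_oversized_window_rejected(self, rng):
        with pytest.raises(ValueError):
            max_pool(random_image(rng, 4, 4, 1), 5)


# --------------------------------------------------------------------------
# spatial pyramid pooling
# --------------------------------------------------------------------------

class TestSPPBlock:
    def _params(self, rng, c, pool_sizes, filters, include_input=True):
        return SPPParams(
            pool_sizes=pool_sizes, filters_per_level=filters,
            include_input=include_input,
            conv_weights=[rng.standard_normal((c, filters)).astype(np.float32)
                          for _ in pool_sizes],
            conv_biases=[rng.standard_normal(filters).astype(np.float32)
                         for _ in pool_sizes],
        )

    def test_output_channel_arithmetic(self, rng):
        x = random_image(rng, 8, 8, 4)
        out = spp_block(x, self._params(rng, 4, (2, 4), 256))
        assert out.shape == (8, 8, 4 + 2 * 256)
        out2 = spp_block(x, self._params(rng, 4, (2,), 256, include_input=False))
        assert out2.shape == (8, 8, 256)

    def test_zero_weights_leave_bias_levels(self, rng):
        x = random_image(rng, 8, 8, 2)
        params = SPPParams(pool_sizes=(2,), filters_per_level=3,
                           include_input=True,
                           conv_weights=[np.zeros((2, 3), np.float32)],
                           conv_biases=[np.zeros(3, np.float32)])
        out = spp_block(x, params)
        np.testing.assert_array_equal(out[..., 2:], 0.0)
        np.testing.assert_array_equal(out[..., :2], x)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_including_ceil_mode(self, seed):
        rng = np.random.default_rng(seed)
        x = random_image(rng, 7, 6, 3)  # 7 and 6 are not multiples of 4
        params = self._params(rng, 3, (2, 4), 5)
        expected = spp_oracle(x, params.pool_sizes, params.conv_weights,
                              params.conv_biases)
        np.testing.assert_allclose(spp_block(x, params), expected, atol=1e-5)

    def test_empty_pool_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            SPPParams(pool_sizes=())

    def test_layer_class_matches_functional(self, rng):
        x = random_image(rng, 8, 8, 3)
        layer = blocks.SPPBlock(3, SPPParams(pool_sizes=(2, 4),
                                             filters_per_level=6), rng=rng)
        params = SPPParams(
            pool_sizes=(2, 4), filters_per_level=6,
            conv_weights=[c.weight.data[0, 0] for c in layer.convs],
            conv_biases=[c.bias.data for c in layer.convs])
        out = layer(nn.Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, spp_block(x, params), atol=1e-5)


# --------------------------------------------------------------------------
# fusion
# --------------------------------------------------------------------------

class TestFusionBlock:
    def test_concat_arithmetic(self, rng):
        a = random_image(rng, 4, 4, 64)
        b = random_image(rng, 4, 4, 64)
        w = rng.standard_normal((3, 3, 128, 64)).astype(np.float32) * 0.05
        out = fusion_block([a, b], w)
        assert out.shape == (4, 4, 64)

    def test_single_input_is_plain_convolution(self, rng):
        x = random_image(rng, 5, 5, 3)
        w = rng.standard_normal((3, 3, 3, 4)).astype(np.float32)
        b = rng.standard_normal(4).astype(np.float32)
        expected = np.maximum(conv2d_oracle(x, w, b), 0.0)
        np.testing.assert_allclose(fusion_block([x], w, b), expected, atol=1e-5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_concat_then_convolve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ins = [random_image(rng, 4, 4, 2), random_image(rng, 4, 4, 2)]
        w = rng.standard_normal((3, 3, 4, 3)).astype(np.float32)
        b = rng.standard_normal(3).astype(np.float32)
        np.testing.assert_allclose(fusion_block(ins, w, b),
                                   fusion_oracle(ins, w, b), atol=1e-6)

    def test_mismatched_dims_and_empty_list(self, rng):
        w = rng.standard_normal((3, 3, 4, 2)).astype(np.float32)
        with pytest.raises(ShapeError):
            fusion_block([random_image(rng, 4, 4, 2),
                          random_image(rng, 5, 4, 2)], w)
        with pytest.raises(ValueError):
            fusion_block([], w)


# --------------------------------------------------------------------------
# conv block
# --------------------------------------------------------------------------

class TestConvBlock:
    def test_zero_network(self, rng):
        x = random_image(rng, 4, 4, 2)
        z = np.zeros((3, 3, 2, 3), np.float32)
        z2 = np.zeros((3, 3, 3, 3), np.float32)
        out = conv_block(x, z, np.zeros(3), z2, np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_1x1_spatial_acts_as_dense(self, rng):
        x = random_image(rng, 1, 1, 4)
        w1 = rng.standard_normal((3, 3, 4, 5)).astype(np.float32)
        w2 = rng.standard_normal((3, 3, 5, 6)).astype(np.float32)
        out = conv_block(x, w1, None, w2, None)
        # with same padding, only the central tap sees the single pixel
        h = np.maximum(x[0, 0] @ w1[1, 1], 0.0)
        expected = np.maximum(h @ w2[1, 1], 0.0)
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = random_image(rng, 8, 8, 1)
        w1 = rng.standard_normal((3, 3, 1, 4)).astype(np.float32)
        b1 = rng.standard_normal(4).astype(np.float32)
        w2 = rng.standard_normal((3, 3, 4, 4)).astype(np.float32)
        b2 = rng.standard_normal(4).astype(np.float32)
        np.testing.assert_allclose(
            conv_block(x, w1, b1, w2, b2),
            conv_block_oracle(x, w1, b1, w2, b2), atol=1e-5)


def test_conv_params_validation():
    with pytest.raises(ConfigurationError):
        ConvParams(filters=0)
    with pytest.raises(ConfigurationError):
        ConvParams(filters=8, kernel_size=2)
    with pytest.raises(ConfigurationError):
        ConvParams(filters=8, padding="valid")
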