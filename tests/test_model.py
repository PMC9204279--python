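"""Architecture contracts: cSE recalibration, residual blocks, scale
transitions, multi-scale fusion and the assembled network."""

import numpy as np
import pytest

from msfaseg.model import (
    AttentionResBlock,
    CSEBlock,
    DownscaleTransition,
    ModelConfig,
    MultiScaleFuse,
    UpscaleTransition,
    build_model,
    count_parameters,
    cse_recalibrate,
)
from msfaseg.nn.autodiff import Tensor


def _rng():
    return np.random.default_rng(0)


class TestCSE:
    def test_zero_excite_weights_halve_the_map(self, rng):
        # excite weights and bias zero -> gate sigmoid(0) = 0.5 per channel
        block = CSEBlock(4, 2, rng)
        block.excite.weight.data[:] = 0
        block.excite.bias.data[:] = 0
        fm = Tensor(rng.standard_normal((2, 4, 5, 5)).astype(np.float32))
        out = cse_recalibrate(fm, block)
        np.testing.assert_allclose(out.data, 0.5 * fm.data, atol=1e-6)

    def test_gap_of_constant_channel(self, rng):
        block = CSEBlock(2, 2, rng)
        fm = np.zeros((1, 2, 3, 3), np.float32)
        fm[0, 0] = 7.0
        fm[0, 1] = -2.0
        from msfaseg.nn.autodiff import global_avg_pool
        np.testing.assert_allclose(global_avg_pool(Tensor(fm)).data,
                                   [[7.0, -2.0]])

    def test_gate_bounded_and_attenuating(self, rng):
        block = CSEBlock(8, 2, rng)
        fm = Tensor(rng.standard_normal((3, 8, 6, 6)).astype(np.float32) * 5)
        s = block.gate(fm).data
        assert np.all(s > 0) and np.all(s < 1)
        out = block(fm).data
        assert np.all(np.abs(out) <= np.abs(fm.data) + 1e-7)

    def test_channel_mismatch_rejected(self, rng):
        block = CSEBlock(4, 2, rng)
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 3, 4, 4), np.float32)))


class TestAttentionResBlock:
    def test_zero_weights_give_zero_map(self, rng):
        block = AttentionResBlock(3, 5, 2, rng)
        for p in block.parameters():
            p.data[:] = 0
        block.eval()  # BN with identity running stats
        x = Tensor(rng.standard_normal((2, 3, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("in_ch,out_ch", [(16, 16), (8, 16)])
    def test_shape_contract(self, rng, in_ch, out_ch):
        block = AttentionResBlock(in_ch, out_ch, 2, rng)
        y = block(Tensor(np.zeros((1, in_ch, 32, 32), np.float32)))
        assert y.data.shape == (1, out_ch, 32, 32)

    def test_saturated_gate_reduces_to_plain_residual_block(self, rng):
        # driving the cSE gate to ~1 must recover main-path + shortcut
        block = AttentionResBlock(4, 4, 2, rng)
        block.eval()
        block.cse.excite.bias.data[:] = 50.0  # sigmoid(50) ~= 1
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        from msfaseg.nn import autodiff as ad
        h = ad.relu(block.bn1(block.conv1(x)))
        h = ad.relu(block.bn2(block.conv2(h)))
        plain = h.data + block.bn_proj(block.proj(x)).data
        np.testing.assert_allclose(block(x).data, plain, atol=1e-5)


class TestTransitions:
    def test_downscale_halves_per_level(self, rng):
        x = Tensor(np.zeros((1, 32, 64, 64), np.float32))
        assert DownscaleTransition(32, 64, 1, rng)(x).data.shape == (1, 64, 32, 32)
        assert DownscaleTransition(32, 64, 2, rng)(x).data.shape == (1, 64, 16, 16)

    def test_upscale_doubles_per_level(self, rng):
        x = Tensor(np.zeros((1, 64, 16, 16), np.float32))
        assert UpscaleTransition(64, 32, 1, rng)(x).data.shape == (1, 32, 32, 32)
        assert UpscaleTransition(64, 32, 2, rng)(x).data.shape == (1, 32, 64, 64)

    def test_zero_levels_rejected(self, rng):
        with pytest.raises(ValueError):
            DownscaleTransition(8, 8, 0, rng)
        with pytest.raises(ValueError):
            UpscaleTransition(8, 8, 0, rng)

    def test_indivisible_dims_rejected(self, rng):
        t = DownscaleTransition(4, 4, 1, rng)
        with pytest.raises(ValueError):
            t(Tensor(np.zeros((1, 4, 7, 8), np.float32)))

    def test_roundtrip_restores_spatial_dims(self, rng):
        x = Tensor(np.zeros((1, 8, 24, 24), np.float32))
        down = DownscaleTransition(8, 16, 1, rng)(x)
        up = UpscaleTransition(16, 8, 1, rng)(down)
        assert up.data.shape[2:] == x.data.shape[2:]


class TestMultiScaleFuse:
    def test_zero_inputs_zero_biases_give_zero(self, rng):
        fuse = MultiScaleFuse([8, 16], rng)  # conv biases init to zero
        outs = fuse([Tensor(np.zeros((1, 8, 16, 16), np.float32)),
                     Tensor(np.zeros((1, 16, 8, 8), np.float32))])
        for o in outs:
            np.testing.assert_allclose(o.data, 0.0)

    def test_two_branch_outputs_assemble_from_transitions(self, rng):
        fuse = MultiScaleFuse([4, 8], rng)
        a = Tensor(np.random.default_rng(1).standard_normal(
            (1, 4, 16, 16)).astype(np.float32))
        b = Tensor(np.random.default_rng(2).standard_normal(
            (1, 8, 8, 8)).astype(np.float32))
        o0, o1 = fuse([a, b])
        assert o0.data.shape == (1, 4, 16, 16)
        assert o1.data.shape == (1, 8, 8, 8)
        # hand assembly from the same transition modules
        np.testing.assert_allclose(
            o0.data, a.data + fuse.transitions[0][1](b).data, atol=1e-6)
        np.testing.assert_allclose(
            o1.data, b.data + fuse.transitions[1][0](a).data, atol=1e-6)

    def test_wrong_branch_count_rejected(self, rng):
        fuse = MultiScaleFuse([4, 8], rng)
        with pytest.raises(ValueError):
            fuse([Tensor(np.zeros((1, 4, 16, 16), np.float32))])


class TestMSFAUNet:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="num_levels"):
            ModelConfig(num_levels=1).validate()
        with pytest.raises(ValueError, match="base_channels"):
            ModelConfig(base_channels=3).validate()

    def test_output_shape_and_range(self):
        model = build_model(ModelConfig(num_levels=3, base_channels=8, seed=0))
        model.eval()
        x = np.random.default_rng(0).random((1, 1, 64, 64)).astype(np.float32)
        y = model(x).data
        assert y.shape == (1, 1, 64, 64)
        assert np.all(y > 0) and np.all(y < 1)
        assert np.isfinite(y).all()

    def test_indivisible_input_rejected(self):
        model = build_model(ModelConfig(num_levels=3, base_channels=8))
        with pytest.raises(ValueError, match="divisible"):
            model(np.zeros((1, 1, 50, 50), np.float32))

    def test_parameter_count_monotone_in_size(self):
        small = build_model(ModelConfig(num_levels=3, base_channels=8))
        big = build_model(ModelConfig(num_levels=4, base_channels=32))
        assert count_parameters(small) < count_parameters(big)

    def test_inference_is_deterministic(self, tiny_model):
        tiny_model.eval()
        x = np.random.default_rng(1).random((2, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model(x).data, tiny_model(x).data)

    def test_no_cross_sample_leakage_in_eval(self, tiny_model):
        tiny_model.eval()
        rng = np.random.default_rng(2)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        base = tiny_model(x).data[1]
        x2 = x.copy()
        x2[0] += rng.random((1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model(x2).data[1], base)

    @pytest.mark.parametrize("levels,base,size", [(2, 4, 32), (3, 8, 40),
                                                  (4, 4, 64), (2, 16, 48)])
    def test_shape_contract_across_configs(self, levels, base, size):
        model = build_model(ModelConfig(num_levels=levels, base_channels=base,
                                        seed=1))
        model.eval()
        x = np.random.default_rng(0).random((1, 1, size, size)).astype(np.float32)
        y = model(x).data
        assert y.shape == (1, 1, size, size)
        assert np.all((y > 0) & (y < 1))

    def test_config_json_roundtrip(self):
        cfg = ModelConfig(num_levels=3, base_channels=16, dropout_rate=0.1)
        assert ModelConfig.from_json(cfg.to_json()) == cfg
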