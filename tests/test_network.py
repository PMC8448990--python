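"""Architecture contracts: shapes, attention-gate semantics, wiring."""

import numpy as np
import pytest

from canalseg.network import (GAU3d, NetworkConfig, SpatialSE, VARIANTS,
                              ConfigurationError, ShapeError, ConvBlock,
                              build_network, combine_attention,
                              load_checkpoint, save_checkpoint)
from canalseg.nn import Tensor

SMALL_CHANNELS = (8, 16, 32, 64)


def small_config(variant="sequential_spatial_first", **kw):
    return NetworkConfig(encoder_channels=SMALL_CHANNELS, variant=variant, seed=1, **kw)


@pytest.fixture(scope="module")
def x_small():
    return Tensor(np.random.default_rng(0).normal(
        size=(1, 1, 16, 32, 32)).astype(np.float32))


class TestConvBlock:
    def test_output_channels_and_preserved_spatial_dims(self, rng):
        block = ConvBlock(1, 32, rng).eval()
        out = block(Tensor(rng.normal(size=(1, 1, 8, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 32, 8, 16, 16)

    def test_relu_output_nonnegative(self, rng):
        block = ConvBlock(2, 4, rng).eval()
        out = block(Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)))
        assert out.data.min() >= 0.0

    def test_repeated_eval_forward_bit_identical(self, rng):
        block = ConvBlock(1, 4, rng).eval()
        x = Tensor(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, block(x).data)


class TestSpatialSE:
    def setup_method(self):
        self.sse = SpatialSE(4, np.random.default_rng(0)).eval()

    def test_saturated_open_gate_is_identity(self, rng):
        self.sse.squeeze.weight.data[:] = 0.0
        self.sse.squeeze.bias.data[:] = 20.0
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
        assert np.abs(self.sse(x).data - x.data).max() < 1e-6

    def test_closed_gate_zeroes_output(self, rng):
        self.sse.squeeze.weight.data[:] = 0.0
        self.sse.squeeze.bias.data[:] = -20.0
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
        assert np.abs(self.sse(x).data).max() < 1e-6

    def test_never_amplifies_activations(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 4, 4, 4)).astype(np.float32))
        out = self.sse(x)
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-7)

    def test_gate_strictly_inside_unit_interval(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
        gate = self.sse.gate(x).data
        assert gate.shape == (1, 1, 4, 4, 4)
        assert np.all(gate > 0.0) and np.all(gate < 1.0)


def _force_gate_ones(gau):
    """Zero the gate conv so BN (eval, zero running mean) sees exactly 0 and
    its shift beta=1 makes conv+BN+ReLU emit exactly 1."""
    gau.gate_conv.weight.data[:] = 0.0
    gau.gate_conv.bias.data[:] = 0.0
    gau.gate_bn.bias.data[:] = 1.0


class TestGAU:
    def make(self, c_low=4, c_high=8):
        return GAU3d(c_low, c_high, (2, 2, 2), np.random.default_rng(0)).eval()

    def test_zeroed_upsample_and_open_gate_reduces_to_low_path(self, rng):
        gau = self.make()
        gau.up.weight.data[:] = 0.0
        gau.up.bias.data[:] = 0.0
        _force_gate_ones(gau)
        f1 = Tensor(rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        f2 = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        from canalseg.nn import relu
        expected = relu(gau.low_bn(gau.low_conv(f1))).data
        np.testing.assert_array_equal(gau(f1, f2).data, expected)

    def test_closed_gate_reduces_to_upsampled_high_path(self, rng):
        gau = self.make()
        gau.gate_conv.weight.data[:] = 0.0
        gau.gate_conv.bias.data[:] = -5.0   # ReLU clamps to exactly 0
        f1 = Tensor(rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        f2 = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        expected = gau.up_bn(gau.up(f2)).data
        np.testing.assert_array_equal(gau(f1, f2).data, expected)

    def test_output_shape_follows_low_level_input(self, rng):
        gau = GAU3d(32, 64, (2, 2, 2), np.random.default_rng(0)).eval()
        f1 = Tensor(np.zeros((1, 32, 32, 64, 64), np.float32))
        f2 = Tensor(np.zeros((1, 64, 16, 32, 32), np.float32))
        assert gau(f1, f2).shape == (1, 32, 32, 64, 64)

    def test_mismatched_spatial_dims_raise_shape_error(self, rng):
        gau = self.make()
        f1 = Tensor(np.zeros((1, 4, 8, 8, 8), np.float32))
        f2 = Tensor(np.zeros((1, 8, 2, 4, 4), np.float32))  # wrong pooling factor
        with pytest.raises(ShapeError, match="shape"):
            gau(f1, f2)


class TestCombineAttention:
    @pytest.fixture()
    def parts(self):
        rng = np.random.default_rng(0)
        sse = SpatialSE(4, rng).eval()
        gau = GAU3d(4, 8, (2, 2, 2), rng).eval()
        f1 = Tensor(np.random.default_rng(1).normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        f2 = Tensor(np.random.default_rng(2).normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        return sse, gau, f1, f2

    def test_all_modes_share_output_shape(self, parts):
        sse, gau, f1, f2 = parts
        shapes = {mode: combine_attention(f1, f2, mode, sse, gau).shape
                  for mode in ("parallel", "sequential_spatial_first",
                               "sequential_channel_first")}
        assert len(set(shapes.values())) == 1

    @pytest.mark.parametrize("mode", ["sequential_spatial_first",
                                      "sequential_channel_first"])
    def test_open_sse_gate_reduces_to_pure_gau(self, parts, mode):
        sse, gau, f1, f2 = parts
        sse.squeeze.weight.data[:] = 0.0
        sse.squeeze.bias.data[:] = 20.0
        out = combine_attention(f1, f2, mode, sse, gau)
        ref = gau(f1, f2)
        assert np.abs(out.data - ref.data).max() < 1e-5

    def test_unknown_mode_lists_valid_ones(self, parts):
        sse, gau, f1, f2 = parts
        with pytest.raises(ValueError, match="parallel"):
            combine_attention(f1, f2, "diagonal", sse, gau)


class TestBuildNetwork:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_full_resolution_logits_for_every_variant(self, variant, x_small):
        model = build_network(small_config(variant)).eval()
        out = model(x_small)
        assert out.shape == (1, 1, 16, 32, 32)

    def test_bottleneck_is_8x_downsampled(self):
        cfg = small_config()
        assert cfg.downsampling == (8, 8, 8)
        # probe the deepest encoder feature directly
        model = build_network(cfg).eval()
        x = Tensor(np.zeros((1, 1, 16, 32, 32), np.float32))
        from canalseg.nn import max_pool3d
        h = x
        for lvl in range(cfg.n_pool + 1):
            if lvl > 0:
                h = max_pool3d(h, cfg.pool_factors)
            h = getattr(model, f"enc{lvl}")(h)
        assert h.shape[2:] == (2, 4, 4)

    def test_indivisible_input_raises_configuration_error(self):
        model = build_network(small_config())
        with pytest.raises(ConfigurationError, match="divisible"):
            model(Tensor(np.zeros((1, 1, 30, 30, 30), np.float32)))

    def test_bad_channel_list_rejected(self):
        with pytest.raises(ConfigurationError, match="n_pool"):
            NetworkConfig(encoder_channels=(8, 16), n_pool=3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError, match="variant"):
            NetworkConfig(variant="resnet")

    def test_sequential_and_parallel_share_parameter_count(self):
        counts = {v: build_network(small_config(v)).num_parameters()
                  for v in ("sequential_spatial_first",
                            "sequential_channel_first", "parallel")}
        assert len(set(counts.values())) == 1

    def test_gau_only_smaller_by_exactly_the_sse_convolutions(self):
        n_seq = build_network(small_config()).num_parameters()
        n_gau = build_network(small_config("gau_only")).num_parameters()
        sse_params = sum(27 * c + 1 for c in SMALL_CHANNELS)
        assert n_seq - n_gau == sse_params

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_gradients_reach_first_encoder_conv(self, variant):
        model = build_network(NetworkConfig(
            encoder_channels=(4, 8, 16, 32), variant=variant, seed=2))
        x = Tensor(np.random.default_rng(3).normal(
            size=(1, 1, 8, 16, 16)).astype(np.float32))
        loss = (model(x) * model(x)).sum()
        loss.backward()
        g = model.enc0.conv1.weight.grad
        assert g is not None and np.abs(g).max() > 0.0

    def test_paper_literal_mode_keeps_depth_axis(self):
        cfg = small_config("gau_only", gau_upsample_mode="paper_literal")
        assert cfg.pool_factors == (1, 2, 2)
        model = build_network(cfg).eval()
        out = model(Tensor(np.zeros((1, 1, 3, 32, 32), np.float32)))
        assert out.shape == (1, 1, 3, 32, 32)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs_and_config(self, tmp_path, x_small):
        model = build_network(small_config("parallel")).eval()
        ref = model(x_small).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, extra={"note": "test"})
        loaded, meta = load_checkpoint(path)
        loaded.eval()
        np.testing.assert_array_equal(loaded(x_small).data, ref)
        assert meta["net_config"]["variant"] == "parallel"
        assert meta["note"] == "test"
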