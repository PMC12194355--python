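"""Architecture blocks against brute-force oracles, plus shape contracts."""

import numpy as np
import pytest

from conftest import conv2d_bruteforce, group_norm_bruteforce
from scintidenoise import model as M
from scintidenoise.dataio import NormalizedImage
from scintidenoise.errors import ConfigurationError, ShapeError
from scintidenoise.nn import Tensor


def _t(arr):
    return Tensor(np.asarray(arr, dtype=float))


def _zero_like(d):
    return {k: Tensor(np.zeros_like(np.asarray(v, dtype=float)))
            for k, v in d.items()}


def _tensorize(d):
    return {k: Tensor(np.asarray(v, dtype=float)) for k, v in d.items()}


class TestMSFB:
    def test_preserves_spatial_size_and_zero_weights(self):
        rng = np.random.default_rng(0)
        p = _tensorize(M.init_msfb(rng, 2, 4))
        x = _t(rng.normal(size=(1, 2, 8, 8)))
        y = M.msfb(x, p, gn_groups=2)
        assert y.shape == (1, 4, 8, 8)
        z = M.msfb(x, _zero_like({k: v.data for k, v in p.items()}),
                   gn_groups=2)
        assert np.all(z.data == 0.0)

    def test_odd_out_channels_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            M.init_msfb(rng, 2, 5)

    def test_three_by_three_branch_against_bruteforce(self):
        """Fusion arranged to pass only the 3x3 branch; compared to a
        hand-computed conv -> group-norm -> relu composition."""
        rng = np.random.default_rng(1)
        cin, cout = 2, 4
        p_np = M.init_msfb(rng, cin, cout)
        half = cout // 2
        p_np["b5.w"] = np.zeros_like(p_np["b5.w"])
        fuse = np.zeros((cout, cout, 1, 1))
        fuse[:half, :half, 0, 0] = np.eye(half)   # route b3 into channels 0..1
        p_np["fuse.w"] = fuse
        x = rng.normal(size=(1, cin, 8, 8))
        got = M.msfb(_t(x), _tensorize(p_np), gn_groups=2).data

        conv3 = conv2d_bruteforce(x, p_np["b3.w"], p_np["b3.b"], padding=1)
        fused = np.concatenate([conv3, np.zeros_like(conv3)], axis=1)
        want = group_norm_bruteforce(fused, p_np["gn.gamma"],
                                     p_np["gn.beta"], groups=2)
        np.testing.assert_allclose(got, np.maximum(want, 0.0), atol=1e-6)


class TestChannelAttention:
    def test_gates_open_unit_interval(self):
        rng = np.random.default_rng(2)
        p = _tensorize(M.init_attention(rng, 4, 2))
        x = rng.normal(size=(2, 4, 6, 6))
        y = M.channel_attention(_t(x), p).data
        gates = y / np.where(x == 0, 1.0, x)
        g = gates[x != 0]
        assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_zero_input_gives_half_gates(self):
        rng = np.random.default_rng(3)
        p = _tensorize(M.init_attention(rng, 4, 2))   # biases are zero-init
        x = np.zeros((1, 4, 5, 5))
        y = M.channel_attention(_t(x), p)
        assert np.all(y.data == 0.0)
        # gate value itself: GAP=0 -> fc1 -> 0 -> relu -> fc2 -> 0 -> sigmoid
        ones = np.ones((1, 4, 5, 5))
        p0 = _zero_like({k: v.data for k, v in p.items()})
        np.testing.assert_allclose(M.channel_attention(_t(ones), p0).data,
                                   0.5 * ones, atol=1e-12)

    def test_diagonal_fc_hand_oracle_two_channels(self):
        # diagonal FC weights decouple the two channels' gates
        p = {"fc1.w": _t(np.eye(2)), "fc1.b": _t(np.zeros(2)),
             "fc2.w": _t(np.eye(2)), "fc2.b": _t(np.zeros(2))}
        x = np.stack([np.full((4, 4), 2.0), np.full((4, 4), 3.0)])[None]
        y = M.channel_attention(_t(x), p).data
        sig = lambda v: 1 / (1 + np.exp(-v))
        np.testing.assert_allclose(y[0, 0], 2.0 * sig(2.0), atol=1e-12)
        np.testing.assert_allclose(y[0, 1], 3.0 * sig(3.0), atol=1e-12)
        # scaling channel 0 leaves channel 1's gate unchanged
        x2 = x.copy()
        x2[0, 0] *= 5.0
        y2 = M.channel_attention(_t(x2), p).data
        np.testing.assert_allclose(y2[0, 1], y[0, 1], atol=1e-12)


class TestDownUpSample:
    def test_downsample_halves_and_matches_subsampled_dense_conv(self):
        rng = np.random.default_rng(4)
        p_np = M.init_downsample(rng, 2)
        x = rng.normal(size=(1, 2, 8, 8))
        got = M.downsample(_t(x), _tensorize(p_np), gn_groups=2).data
        assert got.shape == (1, 2, 4, 4)
        dense = conv2d_bruteforce(x, p_np["w"], p_np["b"], stride=1, padding=1)
        sub = dense[:, :, ::2, ::2]
        want = np.maximum(group_norm_bruteforce(
            sub, p_np["gn.gamma"], p_np["gn.beta"], groups=2), 0.0)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_odd_dims_rejected(self):
        rng = np.random.default_rng(4)
        p = _tensorize(M.init_downsample(rng, 2))
        with pytest.raises(ShapeError):
            M.downsample(_t(np.zeros((1, 2, 7, 8))), p, gn_groups=2)

    def test_upsample_doubles(self):
        rng = np.random.default_rng(5)
        p = _tensorize(M.init_upsample(rng, 4, 2))
        y = M.upsample(_t(rng.normal(size=(1, 4, 8, 8))), p, gn_groups=2)
        assert y.shape == (1, 2, 16, 16)


class TestBottleneckERB:
    def test_bottleneck_is_per_pixel_matrix_product(self):
        rng = np.random.default_rng(6)
        p_np = M.init_bottleneck(rng, 4)
        x = rng.normal(size=(1, 4, 2, 2))
        got = M.bottleneck(_t(x), _tensorize(p_np)).data
        mat = p_np["w"][:, :, 0, 0]          # (2, 4)
        for r in range(2):
            for c in range(2):
                want = np.maximum(mat @ x[0, :, r, c] + p_np["b"], 0.0)
                np.testing.assert_allclose(got[0, :, r, c], want, atol=1e-10)

    def test_bottleneck_channel_minimum(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ConfigurationError):
            M.init_bottleneck(rng, 1)

    def test_erb_zero_weights_is_identity(self):
        rng = np.random.default_rng(7)
        p_np = {k: np.zeros_like(v) for k, v in M.init_erb(rng, 4).items()}
        x = rng.normal(size=(2, 4, 6, 6))
        y = M.erb(_t(x), _tensorize(p_np), gn_groups=2)
        np.testing.assert_array_equal(y.data, x)

    def test_erb_depthwise_separable_against_dense_oracle(self):
        rng = np.random.default_rng(8)
        p_np = M.init_erb(rng, 2)
        x = rng.normal(size=(1, 2, 6, 6))
        got = M.erb(_t(x), _tensorize(p_np), gn_groups=2).data
        dw = conv2d_bruteforce(x, p_np["dw.w"], p_np["dw.b"],
                               padding=1, groups=2)
        pw = conv2d_bruteforce(dw, p_np["pw.w"], p_np["pw.b"])
        inner = np.maximum(group_norm_bruteforce(
            pw, p_np["gn.gamma"], p_np["gn.beta"], groups=2), 0.0)
        np.testing.assert_allclose(got, x + inner, atol=1e-6)


class TestForward:
    @pytest.mark.parametrize("size", [64, 256])
    def test_shape_preserved(self, size, tiny_config, tiny_params):
        rng = np.random.default_rng(9)
        img = NormalizedImage(rng.random((size, size)))
        out = M.forward(tiny_params, tiny_config, img)
        assert out.shape == (size, size)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_indivisible_dims_named_in_error(self, tiny_config, tiny_params):
        img = NormalizedImage(np.zeros((30, 30)))
        with pytest.raises(ShapeError, match="divisible by 4"):
            M.forward(tiny_params, tiny_config, img)

    def test_deterministic_inference(self, tiny_config, tiny_params):
        rng = np.random.default_rng(10)
        img = NormalizedImage(rng.random((32, 32)))
        a = M.forward(tiny_params, tiny_config, img)
        b = M.forward(tiny_params, tiny_config, img)
        np.testing.assert_array_equal(a.values, b.values)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            M.ModelConfig(msfb_kernels=(3, 7))
        with pytest.raises(ConfigurationError):
            M.ModelConfig(encoder_widths=(12,), n_downsamples=1, gn_groups=8)
        with pytest.raises(ConfigurationError):
            M.ModelConfig(output_activation="tanh")


class TestParameterCount:
    def test_hand_tally_tiny_config(self, tiny_config, tiny_params):
        def msfb_n(ci, co):
            return (co // 2 * ci * 9 + co // 2) + (co // 2 * ci * 25 + co // 2) \
                + (co * co + co) + 2 * co

        def att_n(c, r):
            return c * (c // r) + c // r + (c // r) * c + c

        def down_n(c):
            return c * c * 9 + c + 2 * c

        def up_n(ci, co):
            return ci * co * 16 + co + 2 * co

        def erb_n(c):
            return (c * 9 + c) + (c * c + c) + 2 * c

        w1, w2 = tiny_config.encoder_widths
        d1, d2 = tiny_config.decoder_widths
        bneck = tiny_config.bottleneck_channels
        expected = (msfb_n(1, w1) + att_n(w1, 2) + down_n(w1)
                    + msfb_n(w1, w2) + att_n(w2, 2) + down_n(w2)
                    + (bneck * w2 + bneck)
                    + up_n(bneck, d1) + erb_n(d1)
                    + up_n(d1, d2) + erb_n(d2)
                    + (d2 * 9 + 1))
        assert M.count_parameters(tiny_params) == expected

    def test_stable_and_monotone_in_width(self, tiny_config):
        a = M.count_parameters(M.init_parameters(tiny_config))
        b = M.count_parameters(M.init_parameters(tiny_config))
        assert a == b
        wide = M.ModelConfig(encoder_widths=(8, 16), gn_groups=2,
                             attention_reduction=2)
        assert M.count_parameters(M.init_parameters(wide)) > a


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, tiny_config,
                                          tiny_params):
        rng = np.random.default_rng(11)
        img = NormalizedImage(rng.random((16, 16)))
        before = M.forward(tiny_params, tiny_config, img)
        path = tmp_path / "ckpt.npz"
        M.save_checkpoint(path, tiny_params, train_seed=5)
        loaded, meta = M.load_checkpoint(path)
        assert meta["version"] == M.CHECKPOINT_VERSION
        assert meta["train_seed"] == 5
        after = M.forward(loaded, loaded.config, img)
        np.testing.assert_array_equal(before.values, after.values)
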