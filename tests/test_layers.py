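"""Joint layer forward rules against hand-computed scalar oracles."""

import numpy as np
import pytest

from jointmri import autograd as ag
from jointmri.autograd import Parameter, Tensor
from jointmri.layers import (
    ConvBlock,
    JointLayerParams,
    LayerState,
    MixingLogits,
    alternating_forward,
    freq_activation,
    image_activation,
    interleaved_forward,
    mix_inputs,
)

BN_EPS = 1e-5


def _fft2c_np(x):
    # independent centering convention, straight from numpy.fft
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def _ifft2c_np(x):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


def _pairs_fft(v, inverse=False):
    # channelwise transform of an (H, W, 2) stack, computed independently
    c = v[..., 0] + 1j * v[..., 1]
    t = _ifft2c_np(c) if inverse else _fft2c_np(c)
    return np.stack([t.real, t.imag], axis=-1)


def _conv3x3_scalar(x, w, b):
    """Zero-padded 'same' 3x3 cross-correlation via explicit loops."""
    H, W, cin = x.shape
    cout = w.shape[-1]
    out = np.zeros((H, W, cout))
    for p in range(H):
        for q in range(W):
            for co in range(cout):
                acc = b[co]
                for i in range(3):
                    for j in range(3):
                        pi, qj = p + i - 1, q + j - 1
                        if 0 <= pi < H and 0 <= qj < W:
                            for ci in range(cin):
                                acc += w[i, j, ci, co] * x[pi, qj, ci]
                out[p, q, co] = acc
    return out


def _mixing(alpha, beta):
    return MixingLogits(Parameter(float(alpha), "a"), Parameter(float(beta), "b"))


def _identity_block(c_in, c_out, w_val=0.0, b_val=0.0):
    blk = ConvBlock.create(c_in, c_out, np.random.default_rng(0), name="t")
    blk.w.data = np.full((3, 3, c_in, c_out), w_val)
    blk.b.data = np.full(c_out, b_val)
    return blk


class TestFreqActivation:
    def test_zero_maps_to_zero(self):
        assert freq_activation(np.array(0.0)) == 0.0

    @pytest.mark.parametrize(
        "x,expected", [(1.0, 1.5), (-1.0, -1.5), (0.5, 0.5), (-0.5, -0.5), (0.25, 0.25), (3.0, 5.5)]
    )
    def test_piecewise_values(self, x, expected):
        assert freq_activation(np.array(x)) == pytest.approx(expected)

    def test_odd_symmetry_and_strict_monotonicity(self, rng):
        x = rng.normal(scale=2.0, size=10_000)
        assert np.allclose(freq_activation(-x), -freq_activation(x))
        pairs = np.sort(rng.normal(scale=2.0, size=(10_000, 2)), axis=1)
        distinct = pairs[:, 0] < pairs[:, 1]
        assert np.all(
            freq_activation(pairs[distinct, 0]) < freq_activation(pairs[distinct, 1])
        )


class TestImageActivation:
    def test_relu_behaviour_and_idempotence(self):
        assert image_activation(np.array(-3.0)) == 0.0
        assert image_activation(np.array(2.0)) == 2.0
        x = np.random.default_rng(0).normal(size=100)
        once = image_activation(x)
        assert np.array_equal(image_activation(once), once)


class TestMixInputs:
    def test_saturated_alpha_passes_u_through_exactly(self, rng):
        u = Tensor(rng.normal(size=(1, 4, 4, 2)))
        v = Tensor(rng.normal(size=(1, 4, 4, 2)))
        u_hat, _ = mix_inputs(u, v, _mixing(1000.0, 0.0))
        assert np.array_equal(u_hat.data, u.data)

    def test_saturated_negative_beta_gives_pure_inverse_dft(self, rng):
        u = Tensor(rng.normal(size=(1, 4, 4, 2)))
        v = Tensor(rng.normal(size=(1, 4, 4, 2)))
        _, v_hat = mix_inputs(u, v, _mixing(0.0, -1000.0))
        assert np.abs(v_hat.data[0] - _pairs_fft(u.data[0], inverse=True)).max() < 1e-12

    def test_zero_logits_give_half_half_blend(self, rng):
        # the initialization point: u_hat = (u + F v) / 2, checked against
        # an independently computed 4x4 case
        u = Tensor(rng.normal(size=(1, 4, 4, 2)))
        v = Tensor(rng.normal(size=(1, 4, 4, 2)))
        u_hat, v_hat = mix_inputs(u, v, _mixing(0.0, 0.0))
        exp_u = 0.5 * u.data[0] + 0.5 * _pairs_fft(v.data[0])
        exp_v = 0.5 * v.data[0] + 0.5 * _pairs_fft(u.data[0], inverse=True)
        assert np.abs(u_hat.data[0] - exp_u).max() < 1e-12
        assert np.abs(v_hat.data[0] - exp_v).max() < 1e-12

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            mix_inputs(
                Tensor(rng.normal(size=(1, 4, 4, 2))),
                Tensor(rng.normal(size=(1, 4, 5, 2))),
                _mixing(0, 0),
            )


class TestInterleavedLayer:
    def test_zero_kernels_reduce_to_tiled_residual(self, rng):
        u0 = Tensor(rng.normal(size=(1, 4, 4, 2)))
        v0 = Tensor(rng.normal(size=(1, 4, 4, 2)))
        layer = JointLayerParams(
            freq=_identity_block(2, 4), img=_identity_block(2, 4), mixing=_mixing(0, 0)
        )
        state = LayerState(u=u0, v=v0, u0=u0, v0=v0)
        out = interleaved_forward(state, layer)
        # sigma(0) = 0 and relu(0) = 0, so only the tiled residual remains
        assert np.array_equal(out.u.data, np.tile(u0.data, (1, 1, 1, 2)))
        assert np.array_equal(out.v.data, np.tile(v0.data, (1, 1, 1, 2)))

    @pytest.mark.parametrize("h,w", [(4, 4), (5, 7), (8, 6)])
    def test_spatial_dims_preserved(self, rng, h, w):
        u0 = Tensor(rng.normal(size=(1, h, w, 2)))
        v0 = Tensor(rng.normal(size=(1, h, w, 2)))
        layer = JointLayerParams(
            freq=ConvBlock.create(2, 8, np.random.default_rng(0), name="f"),
            img=ConvBlock.create(2, 8, np.random.default_rng(1), name="i"),
            mixing=_mixing(0, 0),
        )
        out = interleaved_forward(LayerState(u0, v0, u0, v0), layer)
        assert out.u.shape == (1, h, w, 8)
        assert out.v.shape == (1, h, w, 8)

    def test_full_layer_matches_scalar_evaluation(self, rng):
        # one layer on a 4x4 2-channel input with hand-set half-valued
        # kernels, against a straight-line loop evaluation of the layer rule
        u0 = rng.normal(size=(4, 4, 2))
        v0 = rng.normal(size=(4, 4, 2))
        layer = JointLayerParams(
            freq=_identity_block(2, 2, w_val=0.5, b_val=0.1),
            img=_identity_block(2, 2, w_val=0.5, b_val=0.1),
            mixing=_mixing(0.0, 0.0),
        )
        out = interleaved_forward(
            LayerState(Tensor(u0[None]), Tensor(v0[None]), Tensor(u0[None]), Tensor(v0[None])),
            layer,
        )
        # oracle: mix -> inference BN (mean 0, var 1) -> conv -> act -> +residual
        u_hat = 0.5 * u0 + 0.5 * _pairs_fft(v0)
        v_hat = 0.5 * v0 + 0.5 * _pairs_fft(u0, inverse=True)
        scale = 1.0 / np.sqrt(1.0 + BN_EPS)
        w = np.full((3, 3, 2, 2), 0.5)
        b = np.full(2, 0.1)
        pre_u = _conv3x3_scalar(u_hat * scale, w, b)
        pre_v = _conv3x3_scalar(v_hat * scale, w, b)
        exp_u = np.where(np.abs(pre_u) > 0.5, 2 * pre_u - np.sign(pre_u) * 0.5, pre_u) + u0
        exp_v = np.maximum(pre_v, 0.0) + v0
        assert np.abs(out.u.data[0] - exp_u).max() < 1e-6
        assert np.abs(out.v.data[0] - exp_v).max() < 1e-6


class TestAlternatingLayer:
    def test_zero_kernels_match_scalar_evaluation(self, rng):
        u0 = rng.normal(size=(4, 4, 2))
        v0 = rng.normal(size=(4, 4, 2))
        layer = JointLayerParams(freq=_identity_block(2, 2), img=_identity_block(2, 2))
        u_next, v = alternating_forward(Tensor(u0[None]), layer, Tensor(u0[None]), Tensor(v0[None]))
        # conv outputs vanish: v = F^-1{u0}; u_next = F{relu(conv(BN(v))) + v0} = F{v0}
        exp_v = _pairs_fft(u0, inverse=True)
        exp_u = _pairs_fft(v0)
        assert np.abs(v.data[0] - exp_v).max() < 1e-12
        assert np.abs(u_next.data[0] - exp_u).max() < 1e-12

    def test_half_valued_kernels_match_scalar_evaluation(self, rng):
        u0 = rng.normal(size=(4, 4, 2))
        v0 = rng.normal(size=(4, 4, 2))
        layer = JointLayerParams(
            freq=_identity_block(2, 2, w_val=0.5, b_val=0.1),
            img=_identity_block(2, 2, w_val=0.5, b_val=0.1),
        )
        u_next, v = alternating_forward(Tensor(u0[None]), layer, Tensor(u0[None]), Tensor(v0[None]))
        scale = 1.0 / np.sqrt(1.0 + BN_EPS)
        w = np.full((3, 3, 2, 2), 0.5)
        b = np.full(2, 0.1)
        pre = _conv3x3_scalar(u0 * scale, w, b)
        act = np.where(np.abs(pre) > 0.5, 2 * pre - np.sign(pre) * 0.5, pre)
        exp_v = _pairs_fft(act + u0, inverse=True)
        pre_i = _conv3x3_scalar(exp_v * scale, w, b)
        exp_u = _pairs_fft(np.maximum(pre_i, 0.0) + v0)
        assert np.abs(v.data[0] - exp_v).max() < 1e-6
        assert np.abs(u_next.data[0] - exp_u).max() < 1e-6

    def test_repeated_application_deterministic(self, rng):
        u0 = Tensor(rng.normal(size=(1, 4, 4, 2)))
        v0 = Tensor(rng.normal(size=(1, 4, 4, 2)))
        layer = JointLayerParams(
            freq=ConvBlock.create(2, 2, np.random.default_rng(0), name="f"),
            img=ConvBlock.create(2, 2, np.random.default_rng(1), name="i"),
        )
        a, _ = alternating_forward(u0, layer, u0, v0)
        b, _ = alternating_forward(u0, layer, u0, v0)
        assert np.array_equal(a.data, b.data)


class TestGeneralizationProperty:
    def test_pure_frequency_mixing_ignores_image_stream(self, rng):
        # s(alpha) = 1, s(beta) = 0: the u-stream must be bit-identical
        # under arbitrary perturbation of the image-stream input
        u0 = Tensor(rng.normal(size=(1, 8, 8, 2)))
        layers = [
            JointLayerParams(
                freq=ConvBlock.create(2 if n == 0 else 8, 8, np.random.default_rng(n), name="f"),
                img=ConvBlock.create(2 if n == 0 else 8, 8, np.random.default_rng(n + 10), name="i"),
                mixing=_mixing(1000.0, -1000.0),
            )
            for n in range(3)
        ]

        def run_u(v0_arr):
            state = LayerState(u=u0, v=Tensor(v0_arr), u0=u0, v0=Tensor(v0_arr))
            for layer in layers:
                state = interleaved_forward(state, layer)
            return state.u.data

        base = run_u(rng.normal(size=(1, 8, 8, 2)))
        perturbed = run_u(rng.normal(size=(1, 8, 8, 2)) * 50.0)
        assert np.array_equal(base, perturbed)

    def test_pure_image_mixing_ignores_frequency_stream(self, rng):
        # s(alpha) = 0, s(beta) = 1: the v-stream reduces to a pure
        # image-space network, independent of the u input
        v0 = Tensor(rng.normal(size=(1, 8, 8, 2)))
        layers = [
            JointLayerParams(
                freq=ConvBlock.create(2 if n == 0 else 8, 8, np.random.default_rng(n), name="f"),
                img=ConvBlock.create(2 if n == 0 else 8, 8, np.random.default_rng(n + 10), name="i"),
                mixing=_mixing(-1000.0, 1000.0),
            )
            for n in range(3)
        ]

        def run_v(u0_arr):
            state = LayerState(u=Tensor(u0_arr), v=v0, u0=Tensor(u0_arr), v0=v0)
            for layer in layers:
                state = interleaved_forward(state, layer)
            return state.v.data

        base = run_v(rng.normal(size=(1, 8, 8, 2)))
        perturbed = run_v(rng.normal(size=(1, 8, 8, 2)) * 50.0)
        assert np.array_equal(base, perturbed)


class TestLayerProperties:
    def test_image_conv_block_shift_equivariant_with_periodic_padding(self, rng):
        blk = ConvBlock.create(4, 6, np.random.default_rng(0), name="b", pad_mode="periodic")
        x = rng.normal(size=(1, 8, 8, 4))
        out = image_activation(blk.apply(Tensor(x))).data
        shifted_in = np.roll(x, (3, 2), axis=(1, 2))
        out_shifted = image_activation(blk.apply(Tensor(shifted_in))).data
        assert np.abs(np.roll(out, (3, 2), axis=(1, 2)) - out_shifted).max() < 1e-12

    def test_forward_finite_for_large_magnitude_inputs(self, rng):
        u0 = Tensor(rng.normal(size=(1, 8, 8, 2)) * 1e3)
        v0 = Tensor(rng.normal(size=(1, 8, 8, 2)) * 1e3)
        layer = JointLayerParams(
            freq=ConvBlock.create(2, 8, np.random.default_rng(0), name="f"),
            img=ConvBlock.create(2, 8, np.random.default_rng(1), name="i"),
            mixing=_mixing(0, 0),
        )
        out = interleaved_forward(LayerState(u0, v0, u0, v0), layer)
        assert np.all(np.isfinite(out.u.data))
        assert np.all(np.isfinite(out.v.data))
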