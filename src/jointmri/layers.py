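"""Joint frequency/image-space network layers.

Two layer families couple a frequency-space feature stream ``u`` and an
image-space stream ``v`` inside a single network:

* **Interleaved** — the streams run in parallel and are blended at every
  layer by learned scalar mixing coefficients ``s(alpha), s(beta)`` in
  (0, 1):

  .. math::

      \\hat u_n = s(\\alpha_n) u_n + (1 - s(\\alpha_n))\\,\\mathcal{F}\\{v_n\\},
      \\qquad
      \\hat v_n = s(\\beta_n) v_n + (1 - s(\\beta_n))\\,\\mathcal{F}^{-1}\\{u_n\\},

  followed per stream by batch norm, a 3×3 convolution, a space-specific
  activation, and a residual add of the 2-channel network input.  With
  ``s(alpha)=1, s(beta)=0`` the layer degenerates to a pure frequency-space
  network; with ``s(alpha)=0, s(beta)=1`` to a pure image-space network.

* **Alternating** — each layer applies a frequency-space convolution, hops
  to image space through the inverse DFT, applies an image-space
  convolution, and hops back.

Real and imaginary parts are carried as separate real channels; the DFTs
act per complex channel pair.  The frequency-space activation is an odd,
strictly increasing piecewise-linear map (identity on [-1/2, 1/2], slope 2
outside) whose magnitude grows with the input everywhere — unlike ReLU,
which would flatten the large negative values that are common in k-space.
The image-space activation is the usual ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor, as_tensor

__all__ = [
    "freq_activation",
    "image_activation",
    "MixingLogits",
    "ConvBlock",
    "JointLayerParams",
    "LayerState",
    "mix_inputs",
    "interleaved_forward",
    "alternating_forward",
]


def freq_activation(x):
    """Frequency-space nonlinearity (elementwise, odd, strictly increasing).

    sigma(x) = x on [-1/2, 1/2], 2x - 1/2 for x > 1/2, 2x + 1/2 for
    x < -1/2.  Slope 1 inside the unit band, slope 2 in the wings, so the
    magnitude of the response grows with the magnitude of the input for
    both signs.  Accepts a plain array (returns an array) or a
    :class:`~jointmri.autograd.Tensor` (returns a Tensor on the tape).
    """
    if isinstance(x, Tensor):
        d = x.data
        out_data = _freq_act_np(d)
        slope = np.where(np.abs(d) > 0.5, 2.0, 1.0)

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * slope)

        return Tensor(out_data, parents=(x,), backward=backward)
    return _freq_act_np(np.asarray(x, dtype=np.float64))


def _freq_act_np(d: np.ndarray) -> np.ndarray:
    return np.where(d > 0.5, 2.0 * d - 0.5, np.where(d < -0.5, 2.0 * d + 0.5, d))


def freq_activation_literal(x):
    """Literal composition x + ReLU(x - 1/2) + ReLU(-x + 1/2).

    Kept as a swappable alternative to :func:`freq_activation` for
    comparison: this form evaluates to the constant 1/2 for all x < 1/2
    (the two ReLU branches cancel the identity term there), so it is
    neither odd nor strictly increasing.  Pass it as the ``freq_act``
    argument of the layer forwards to experiment with it.
    """
    if isinstance(x, Tensor):
        return x + ag.relu(x - 0.5) + ag.relu(0.5 - x)
    d = np.asarray(x, dtype=np.float64)
    return d + np.maximum(d - 0.5, 0.0) + np.maximum(0.5 - d, 0.0)


def image_activation(x):
    """Image-space nonlinearity: ReLU on real and imaginary channels."""
    if isinstance(x, Tensor):
        return ag.relu(x)
    d = np.asarray(x, dtype=np.float64)
    return np.maximum(d, 0.0)


@dataclass
class MixingLogits:
    """Scalar logits for the Interleaved mixing coefficients.

    The effective coefficients are ``s(alpha), s(beta)`` with
    ``s(x) = 1/(1+exp(-x))``, hence always in (0, 1); logits of 0 give the
    0.5/0.5 initialization.
    """

    alpha: Parameter
    beta: Parameter

    @classmethod
    def zeros(cls, name: str = "mixing") -> "MixingLogits":
        return cls(Parameter(0.0, f"{name}.alpha"), Parameter(0.0, f"{name}.beta"))


@dataclass
class ConvBlock:
    """Batch norm -> 3×3 'same' convolution bundle for one stream.

    The normalization acts on the block's *input* channels; the convolution
    maps them to ``w.shape[-1]`` output features.
    """

    w: Parameter  # (kh, kw, Cin, Cout)
    b: Parameter  # (Cout,)
    bn_gamma: Parameter  # (Cin,)
    bn_beta: Parameter  # (Cin,)
    bn_state: dict = field(default_factory=dict)
    pad_mode: str = "zeros"

    @classmethod
    def create(
        cls,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        name: str = "block",
        pad_mode: str = "zeros",
    ) -> "ConvBlock":
        # He-normal fan-in initialization for the convolution weights
        std = np.sqrt(2.0 / (kernel * kernel * c_in))
        w = rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out))
        return cls(
            w=Parameter(w, f"{name}.w"),
            b=Parameter(np.zeros(c_out), f"{name}.b"),
            bn_gamma=Parameter(np.ones(c_in), f"{name}.bn_gamma"),
            bn_beta=Parameter(np.zeros(c_in), f"{name}.bn_beta"),
            bn_state={
                "running_mean": np.zeros(c_in),
                "running_var": np.ones(c_in),
            },
            pad_mode=pad_mode,
        )

    def apply(self, x, training: bool = False) -> Tensor:
        """BN then convolution (activation is applied by the caller)."""
        x = as_tensor(x)
        h = ag.batch_norm(x, self.bn_gamma, self.bn_beta, self.bn_state, training)
        return ag.conv2d(h, self.w, self.b, pad_mode=self.pad_mode)

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b, self.bn_gamma, self.bn_beta]


@dataclass
class JointLayerParams:
    """Parameters for one joint layer: one block per stream plus mixing."""

    freq: ConvBlock
    img: ConvBlock
    mixing: MixingLogits | None = None  # present for Interleaved layers

    def parameters(self) -> list[Parameter]:
        out = self.freq.parameters() + self.img.parameters()
        if self.mixing is not None:
            out += [self.mixing.alpha, self.mixing.beta]
        return out


@dataclass
class LayerState:
    """Running state of a joint stack: the two streams and the retained
    2-channel network inputs used as residuals."""

    u: Tensor  # frequency stream (B, H, W, C)
    v: Tensor  # image stream (B, H, W, C)
    u0: Tensor  # network frequency input (B, H, W, 2)
    v0: Tensor  # network image input (B, H, W, 2)


def _tiled(residual: Tensor, c_out: int) -> Tensor:
    """Tile the 2-channel residual across the output complex pairs."""
    if c_out % 2 != 0:
        raise ValueError("output channel count must be even")
    n = c_out // 2
    return residual if n == 1 else ag.tile_pairs(residual, n)


def mix_inputs(u, v, m: MixingLogits) -> tuple[Tensor, Tensor]:
    """Blend the streams with their cross-space transforms.

    u_hat = s(alpha)·u + (1-s(alpha))·F{v};
    v_hat = s(beta)·v + (1-s(beta))·F^{-1}{u}, with the DFTs applied per
    complex channel pair.
    """
    u, v = as_tensor(u), as_tensor(v)
    if u.shape != v.shape:
        raise ValueError(f"stream shape mismatch: {u.shape} vs {v.shape}")
    sa = ag.sigmoid(m.alpha)
    sb = ag.sigmoid(m.beta)
    u_hat = sa * u + (1.0 - sa) * ag.fft_pairs(v)
    v_hat = sb * v + (1.0 - sb) * ag.ifft_pairs(u)
    return u_hat, v_hat


def interleaved_forward(
    state: LayerState, p: JointLayerParams, training: bool = False, freq_act=None
) -> LayerState:
    """One Interleaved layer: mix, then BN -> conv -> activation -> residual
    per stream (frequency activation on u, ReLU on v).  ``freq_act``
    swaps in an alternative frequency-space nonlinearity."""
    if p.mixing is None:
        raise ValueError("Interleaved layers require mixing logits")
    freq_act = freq_act or freq_activation
    u_hat, v_hat = mix_inputs(state.u, state.v, p.mixing)
    c_out = p.freq.w.shape[-1]
    u_next = freq_act(p.freq.apply(u_hat, training)) + _tiled(state.u0, c_out)
    v_next = image_activation(p.img.apply(v_hat, training)) + _tiled(state.v0, c_out)
    return LayerState(u=u_next, v=v_next, u0=state.u0, v0=state.v0)


def alternating_forward(
    u, p: JointLayerParams, u0, v0, training: bool = False, freq_act=None
) -> tuple[Tensor, Tensor]:
    """One Alternating layer.

    v      = F^{-1}{ sigma(freq_conv(BN(u))) + u0 }
    u_next = F{ relu(img_conv(BN(v))) + v0 }

    Residuals are added *inside* the transforms, per the layer definition.
    Returns ``(u_next, v)``.
    """
    u, u0, v0 = as_tensor(u), as_tensor(u0), as_tensor(v0)
    freq_act = freq_act or freq_activation
    c_f = p.freq.w.shape[-1]
    v = ag.ifft_pairs(freq_act(p.freq.apply(u, training)) + _tiled(u0, c_f))
    c_i = p.img.w.shape[-1]
    u_next = ag.fft_pairs(image_activation(p.img.apply(v, training)) + _tiled(v0, c_i))
    return u_next, v
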