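"""The four reconstruction architectures and exact parameter accounting.

``interleaved`` and ``alternating`` stack 10 joint layers (one frequency
and one image 3×3/64-feature convolution each); ``frequency`` and ``image``
are ablation baselines with 20 single-space convolutions so the total
convolution count matches.  A final 3×3 convolution projects the 64-feature
stream to the 2-channel complex output.  With the defaults the trainable
parameter totals are 670,622 (interleaved) and 706,438 (alternating,
frequency, image).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor, as_tensor
from .fourier import IMAGE, KSPACE, ComplexGrid, grid_to_channels, channels_to_grid
from .layers import (
    ConvBlock,
    JointLayerParams,
    LayerState,
    MixingLogits,
    alternating_forward,
    freq_activation,
    image_activation,
    interleaved_forward,
)

VARIANTS = ("interleaved", "alternating", "frequency", "image")

__all__ = [
    "NetworkConfig",
    "ReconNetwork",
    "build_network",
    "forward",
    "apply_network",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``n_layers`` counts joint layers for the joint variants; the
    single-space baselines use ``2*n_layers`` convolutions to match the
    joint networks' convolution budget.
    """

    variant: str = "interleaved"
    n_layers: int = 10
    features: int = 64
    kernel: int = 3
    input_channels: int = 2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unsupported variant {self.variant!r}; choose from {VARIANTS}")
        if self.features % 2 != 0:
            raise ValueError("features must be even (interleaved re/im channel pairs)")


@dataclass
class ReconNetwork:
    """An ordered stack of layer parameters plus the final projection."""

    config: NetworkConfig
    layers: list  # JointLayerParams (joint variants) or ConvBlock (single-space)
    final_w: Parameter
    final_b: Parameter

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend([self.final_w, self.final_b])
        return out

    def parameter_partition(self) -> dict[str, str]:
        """Map parameter name -> 'freq' | 'image' | 'mixing' stream label.

        The final projection acts on the frequency stream except in the
        pure image-space variant.
        """
        labels: dict[str, str] = {}
        for p in self.parameters():
            if "mixing" in p.name:
                labels[p.name] = "mixing"
            elif ".img" in p.name or self.config.variant == "image":
                labels[p.name] = "image"
            else:
                labels[p.name] = "freq"
        return labels


def build_network(cfg: NetworkConfig, rng: np.random.Generator | int | None = 0) -> ReconNetwork:
    """Construct a network with He-normal convolution weights, zero biases,
    identity batch norm, and 0.5/0.5 mixing initialization."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c_in0 = cfg.input_channels
    f = cfg.features
    k = cfg.kernel
    layers: list = []
    if cfg.variant in ("interleaved", "alternating"):
        for n in range(cfg.n_layers):
            if cfg.variant == "interleaved":
                cf = ci = c_in0 if n == 0 else f
            else:
                # alternating: the image conv always sees the 64-feature v
                cf = c_in0 if n == 0 else f
                ci = f
            layer = JointLayerParams(
                freq=ConvBlock.create(cf, f, rng, k, name=f"layer{n}.freq"),
                img=ConvBlock.create(ci, f, rng, k, name=f"layer{n}.img"),
                mixing=MixingLogits.zeros(f"layer{n}.mixing")
                if cfg.variant == "interleaved"
                else None,
            )
            layers.append(layer)
    else:
        for n in range(2 * cfg.n_layers):
            c_in = c_in0 if n == 0 else f
            layers.append(ConvBlock.create(c_in, f, rng, k, name=f"layer{n}.{'freq' if cfg.variant == 'frequency' else 'img'}"))
    std = np.sqrt(2.0 / (k * k * f))
    final_w = Parameter(rng.normal(0.0, std, size=(k, k, f, 2)), "final.w")
    final_b = Parameter(np.zeros(2), "final.b")
    return ReconNetwork(config=cfg, layers=layers, final_w=final_w, final_b=final_b)


def count_parameters(net: ReconNetwork) -> int:
    """Total trainable parameters: convolution weights and biases, batch
    norm scale/shift, and mixing logits (running BN statistics excluded)."""
    return int(sum(p.data.size for p in net.parameters()))


def apply_network(net: ReconNetwork, u0, training: bool = False) -> tuple[Tensor, Tensor]:
    """Run the network on a batched k-space feature stack.

    Parameters
    ----------
    net : ReconNetwork
    u0 : array or Tensor, shape (B, H, W, 2)
        Corrupted k-space as interleaved (re, im) channels.
    training : bool
        Batch norm mode.

    Returns
    -------
    (freq_out, image_out) : Tensor pair, each (B, H, W, 2)
        The k-space prediction and its inverse DFT (for the ``image``
        variant the network output itself is the image prediction and the
        k-space entry is its forward DFT).
    """
    u0 = as_tensor(u0)
    v0 = ag.ifft_pairs(u0)
    cfg = net.config
    if cfg.variant == "interleaved":
        state = LayerState(u=u0, v=v0, u0=u0, v0=v0)
        for layer in net.layers:
            state = interleaved_forward(state, layer, training)
        freq_out = ag.conv2d(state.u, net.final_w, net.final_b)
        return freq_out, ag.ifft_pairs(freq_out)
    if cfg.variant == "alternating":
        u = u0
        for layer in net.layers:
            u, _ = alternating_forward(u, layer, u0, v0, training)
        freq_out = ag.conv2d(u, net.final_w, net.final_b)
        return freq_out, ag.ifft_pairs(freq_out)
    if cfg.variant == "frequency":
        u = u0
        for block in net.layers:
            c_out = block.w.shape[-1]
            res = u0 if c_out == 2 else ag.tile_pairs(u0, c_out // 2)
            u = freq_activation(block.apply(u, training)) + res
        freq_out = ag.conv2d(u, net.final_w, net.final_b)
        return freq_out, ag.ifft_pairs(freq_out)
    # image variant: consume the zero-filled image, emit the image directly
    v = v0
    for block in net.layers:
        c_out = block.w.shape[-1]
        res = v0 if c_out == 2 else ag.tile_pairs(v0, c_out // 2)
        v = image_activation(block.apply(v, training)) + res
    image_out = ag.conv2d(v, net.final_w, net.final_b)
    return ag.fft_pairs(image_out), image_out


def forward(net: ReconNetwork, corrupted: ComplexGrid) -> tuple[ComplexGrid, ComplexGrid]:
    """Inference-mode forward pass on a single k-space grid.

    Returns the k-space estimate and the image estimate (its inverse DFT).
    """
    if isinstance(corrupted, ComplexGrid):
        if corrupted.space != KSPACE:
            raise ValueError("forward expects a k-space grid")
        arr = corrupted.values
    else:
        arr = np.asarray(corrupted, dtype=np.complex128)
    if not np.all(np.isfinite(arr)):
        raise ValueError("forward requires finite input")
    u0 = grid_to_channels(arr)[None]
    freq_out, image_out = apply_network(net, u0, training=False)
    f_hat = channels_to_grid(freq_out.data[0])
    i_hat = channels_to_grid(image_out.data[0])
    return ComplexGrid(f_hat, KSPACE), ComplexGrid(i_hat, IMAGE)


# ---------------------------------------------------------------------------
# checkpoints: one .npz mapping hierarchical parameter names to arrays
# ---------------------------------------------------------------------------

def _bn_states(net: ReconNetwork):
    for i, layer in enumerate(net.layers):
        if isinstance(layer, JointLayerParams):
            yield f"layer{i}.freq", layer.freq.bn_state
            yield f"layer{i}.img", layer.img.bn_state
        else:
            yield f"layer{i}", layer.bn_state


def save_checkpoint(net: ReconNetwork, path) -> None:
    arrays = {f"param/{p.name}": p.data for p in net.parameters()}
    for prefix, state in _bn_states(net):
        arrays[f"bn/{prefix}.running_mean"] = state["running_mean"]
        arrays[f"bn/{prefix}.running_var"] = state["running_var"]
    cfg = net.config
    arrays["config"] = np.frombuffer(
        json.dumps(
            {
                "variant": cfg.variant,
                "n_layers": cfg.n_layers,
                "features": cfg.features,
                "kernel": cfg.kernel,
                "input_channels": cfg.input_channels,
            }
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ReconNetwork:
    with np.load(path) as data:
        cfg = NetworkConfig(**json.loads(bytes(data["config"].tobytes()).decode()))
        net = build_network(cfg, rng=0)
        by_name = {p.name: p for p in net.parameters()}
        for key in data.files:
            if key.startswith("param/"):
                by_name[key[len("param/") :]].data = data[key].copy()
        for prefix, state in _bn_states(net):
            state["running_mean"] = data[f"bn/{prefix}.running_mean"].copy()
            state["running_var"] = data[f"bn/{prefix}.running_var"].copy()
    return net
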