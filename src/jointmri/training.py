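"""Training objectives and the optimization loop.

The reconstruction loss is evaluated on the network's image-space output
against the target image (for the frequency-space losses both are pushed
through the DFT first).  Supported losses:

========== =============================================================
freq_l1     mean |Δre| + |Δim| of the k-space representations
image_l1    mean |Δre| + |Δim| in image space
joint_l1    image_l1 + 0.1 · freq_l1 (weight configurable)
l2          mean (Δre² + Δim²) in image space
neg_ssim    negated SSIM of the magnitude images
neg_ms_ssim negated multiscale SSIM of the magnitude images
neg_psnr    negated PSNR (dB) of the magnitude images
========== =============================================================

Optimization uses Adam (learning rate 0.001 by default); training is
deterministic for a fixed seed and aborts with a diagnostic on divergence.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor, as_tensor
from .fourier import channels_to_grid
from .networks import ReconNetwork, apply_network
from .ssim import ms_ssim_tensor, ssim_tensor

LOSSES = (
    "freq_l1",
    "image_l1",
    "joint_l1",
    "neg_ssim",
    "neg_ms_ssim",
    "neg_psnr",
    "l2",
)

__all__ = ["TrainingConfig", "Adam", "compute_loss", "loss_tensor", "train", "LOSSES"]


@dataclass
class TrainingConfig:
    loss: str = "image_l1"
    lr: float = 0.001
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    joint_freq_weight: float = 0.1  # weight of the k-space term in joint_l1
    patience: int = 10  # early stopping on validation SSIM plateau
    early_stopping: bool = False

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {LOSSES}")


def _mag2d(t: Tensor) -> Tensor:
    # smooth magnitude of an (H, W, 2) channel tensor; the tiny floor
    # keeps the gradient finite at exact zeros
    re = _slice_channel(t, 0)
    im = _slice_channel(t, 1)
    return ag.sqrt(ag.square(re) + ag.square(im), eps=1e-16)


def _slice_channel(x: Tensor, c: int) -> Tensor:
    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[..., c] = g
            x._accumulate(full)

    return Tensor(x.data[..., c], parents=(x,), backward=backward)


def _batch_slice(x: Tensor, b: int) -> Tensor:
    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[b] = g
            x._accumulate(full)

    return Tensor(x.data[b], parents=(x,), backward=backward)


def _l1(pred: Tensor, target: np.ndarray) -> Tensor:
    # mean over pixels of |Δre| + |Δim|  ==  2 × mean over all entries
    diff = pred - Tensor(target)
    return ag.mean(ag.absolute(diff)) * 2.0


def loss_tensor(
    name: str,
    pred_image: Tensor,
    target_image: np.ndarray,
    joint_freq_weight: float = 0.1,
) -> Tensor:
    """Differentiable loss on batched (B, H, W, 2) image predictions."""
    if name not in LOSSES:
        raise ValueError(f"unknown loss {name!r}; choose from {LOSSES}")
    target_image = np.asarray(target_image, dtype=np.float64)
    if pred_image.shape != target_image.shape:
        raise ValueError(
            f"shape mismatch: {pred_image.shape} vs {target_image.shape}"
        )
    if name == "image_l1":
        return _l1(pred_image, target_image)
    if name == "freq_l1":
        from .fourier import fft2c, grid_to_channels

        pred_k = ag.fft_pairs(pred_image)
        target_k = np.stack(
            [
                grid_to_channels(fft2c(channels_to_grid(t)))
                for t in target_image
            ]
        )
        return _l1(pred_k, target_k)
    if name == "joint_l1":
        return loss_tensor("image_l1", pred_image, target_image) + (
            loss_tensor("freq_l1", pred_image, target_image) * joint_freq_weight
        )
    if name == "l2":
        diff = pred_image - Tensor(target_image)
        return ag.mean(ag.square(diff)) * 2.0
    # magnitude-image losses, averaged over the batch
    B = pred_image.shape[0]
    terms: list[Tensor] = []
    for b in range(B):
        pred_b = _batch_slice(pred_image, b)
        pmag = _mag2d(pred_b)
        tmag = np.abs(channels_to_grid(target_image[b]))
        dr = max(float(tmag.max()), 1e-12)
        if name == "neg_ssim":
            terms.append(ssim_tensor(pmag, tmag, dr))
        elif name == "neg_ms_ssim":
            terms.append(ms_ssim_tensor(pmag, tmag, dr))
        else:  # neg_psnr
            mse = ag.mean(ag.square(pmag - Tensor(tmag)))
            log10 = float(np.log(10.0))
            psnr = (ag.log(ag.clamp_min(mse, 1e-300)) * (-10.0 / log10)) + (
                20.0 * np.log10(dr)
            )
            terms.append(psnr)
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return -(acc * (1.0 / B))


def _as_batched_channels(x) -> np.ndarray:
    from .fourier import ComplexGrid, grid_to_channels

    if isinstance(x, ComplexGrid):
        x = x.values
    x = np.asarray(x)
    if np.iscomplexobj(x):
        if x.ndim == 2:
            return grid_to_channels(x)[None]
        return np.stack([grid_to_channels(s) for s in x])
    x = x.astype(np.float64)
    if x.ndim == 3 and x.shape[-1] == 2:
        return x[None]
    if x.ndim == 4 and x.shape[-1] == 2:
        return x
    raise ValueError(f"cannot interpret array of shape {x.shape} as images")


def compute_loss(name: str, pred_image, target_image, joint_freq_weight: float = 0.1) -> float:
    """Scalar loss between prediction and target (grids, complex arrays,
    H×W×2 channel arrays, or batches thereof)."""
    pred = _as_batched_channels(pred_image)
    target = _as_batched_channels(target_image)
    return loss_tensor(name, Tensor(pred), target, joint_freq_weight).item()


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]


def _val_ssim(model, kspace: np.ndarray, target: np.ndarray) -> float:
    from .evaluation import ssim as ssim_metric

    scores = []
    for i in range(kspace.shape[0]):
        _, img = _model_apply(model, kspace[i : i + 1], training=False)
        pmag = np.abs(channels_to_grid(img.data[0]))
        tmag = np.abs(channels_to_grid(target[i]))
        scores.append(ssim_metric(pmag, tmag))
    return float(np.mean(scores))


def _model_apply(model, u0, training: bool):
    """Dispatch to a plain network or an unrolled model."""
    if isinstance(model, ReconNetwork):
        return apply_network(model, u0, training=training)
    return model.apply(u0, training=training)


def train(
    model,
    dataset: dict,
    cfg: TrainingConfig,
    resume_state: dict | None = None,
):
    """Optimize a network (or unrolled model) on a task dataset.

    ``dataset`` holds ``kspace_corrupted`` / ``image_target`` arrays of
    shape (n, H, W, 2) plus optional ``split_train`` / ``split_val`` index
    arrays (all slices train when absent).  Returns
    ``(model, history, state)`` where ``history`` records per-epoch mean
    training loss and validation SSIM and ``state`` can be passed back as
    ``resume_state`` to continue a run deterministically.
    """
    kspace = np.asarray(dataset["kspace_corrupted"], dtype=np.float64)
    target = np.asarray(dataset["image_target"], dtype=np.float64)
    n = kspace.shape[0]
    if n == 0:
        raise ValueError("dataset is empty")
    train_idx = np.asarray(dataset.get("split_train", np.arange(n)))
    val_idx = np.asarray(dataset.get("split_val", []), dtype=int)

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: dict = {"train_loss": [], "val_ssim": []}
    start_epoch = 0
    if resume_state is not None:
        opt.load_state_dict(resume_state["optimizer"])
        rng.bit_generator.state = resume_state["rng_state"]
        start_epoch = resume_state["epoch"]
        history = copy.deepcopy(resume_state["history"])

    best_val = -np.inf
    stale = 0
    for epoch in range(start_epoch, cfg.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(perm), cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            u0 = Tensor(kspace[idx])
            _, img_out = _model_apply(model, u0, training=True)
            loss = loss_tensor(cfg.loss, img_out, target[idx], cfg.joint_freq_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if len(val_idx) > 0:
            vs = _val_ssim(model, kspace[val_idx], target[val_idx])
            history["val_ssim"].append(vs)
            if cfg.early_stopping:
                if vs > best_val + 1e-6:
                    best_val, stale = vs, 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
    state = {
        "optimizer": opt.state_dict(),
        "rng_state": rng.bit_generator.state,
        "epoch": len(history["train_loss"]),
        "history": copy.deepcopy(history),
    }
    return model, history, state
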