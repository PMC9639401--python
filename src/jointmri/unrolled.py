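"""Data-consistency reconstruction: hard substitution and unrolled solves.

For undersampled acquisition the measured k-space lines are exact samples
of the desired output, so a reconstruction can be made consistent with
them either by *hard* substitution (copy the acquired lines verbatim into
the network output) or through the regularized least-squares update used
by unrolled optimization networks:

    x* = argmin_x ||M ∘ F x - b||^2 + lam ||x - z||^2,

where F is the (unitary, centered) DFT, M the 0/1 line mask, b the
acquired k-space and z the current regularizer output.  Single coil, the
problem decouples per k-space coefficient and has the closed form

    x* = F^{-1} [ (M ∘ b + lam F z) / (M + lam) ].

A conjugate-gradient solver covers the general case (e.g. with coil
sensitivity weighting) and must agree with the closed form when both
apply.  An unrolled network repeats K blocks of (learned regularizer,
analytical DC update).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .fourier import IMAGE, KSPACE, ComplexGrid, fft2c, ifft2c
from .corruption import SamplingMask

__all__ = [
    "UnrolledConfig",
    "hard_data_consistency",
    "dc_solve",
    "unrolled_forward",
    "SenseOperator",
]


@dataclass
class UnrolledConfig:
    """K unrolled iterations with a trainable DC weight ``dc_lambda``
    (initialized to 0.05) and weight sharing across iterations."""

    K: int = 5
    layers_per_iter: int = 5
    dc_lambda: float = 0.05
    dc_solver: str = "closed_form"
    share_weights: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.dc_lambda < 0:
            raise ValueError("dc_lambda must be nonnegative")
        if self.dc_solver not in ("closed_form", "conjugate_gradient"):
            raise ValueError(f"unknown dc solver {self.dc_solver!r}")


def _values(x, space: str) -> np.ndarray:
    if isinstance(x, ComplexGrid):
        return x.values
    return np.asarray(x, dtype=np.complex128)


def hard_data_consistency(
    pred: ComplexGrid | np.ndarray,
    acquired: ComplexGrid | np.ndarray,
    mask: SamplingMask,
) -> ComplexGrid:
    """Copy the acquired lines verbatim into the prediction (idempotent;
    kept lines match the acquisition bit-for-bit)."""
    p = _values(pred, KSPACE)
    a = _values(acquired, KSPACE)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    if p.shape[1] != mask.line_kept.shape[0]:
        raise ValueError("mask width does not match the grids")
    out = p.copy()
    out[:, mask.line_kept] = a[:, mask.line_kept]
    return ComplexGrid(out, KSPACE)


def dc_solve(
    z: ComplexGrid | np.ndarray,
    b: ComplexGrid | np.ndarray,
    mask: SamplingMask,
    lam: float,
    solver: str = "closed_form",
    cg_tol: float = 1e-12,
) -> ComplexGrid:
    """Solve argmin_x ||M F x - b||^2 + lam ||x - z||^2 (single coil).

    ``lam`` must be positive unless the mask keeps every line (with an
    incomplete mask and lam = 0 the problem is underdetermined).
    """
    zv = _values(z, IMAGE)
    bv = _values(b, KSPACE)
    m = mask.line_kept.astype(float)[None, :]
    if lam <= 0:
        if not mask.line_kept.all():
            raise ValueError("lam = 0 with an incomplete mask is underdetermined")
        if lam < 0:
            raise ValueError("lam must be nonnegative")
    if solver == "closed_form":
        num = m * bv + lam * fft2c(zv)
        out = ifft2c(num / (m + lam))
        return ComplexGrid(out, IMAGE)
    if solver != "conjugate_gradient":
        raise ValueError(f"unknown solver {solver!r}")
    H, W = zv.shape
    mg = np.broadcast_to(m, (H, W))

    def matvec(xflat):
        x = xflat.reshape(H, W)
        return (ifft2c(mg * fft2c(x)) + lam * x).ravel()

    A = LinearOperator((H * W, H * W), matvec=matvec, dtype=np.complex128)
    rhs = (ifft2c(mg * bv) + lam * zv).ravel()
    sol, info = cg(A, rhs, rtol=cg_tol, maxiter=500)
    if info != 0:
        raise RuntimeError(f"CG did not converge (info={info})")
    return ComplexGrid(sol.reshape(H, W), IMAGE)


@dataclass
class SenseOperator:
    """Forward operator with smooth coil sensitivity maps (optional
    multi-coil generalization; CG-only solve path)."""

    maps: np.ndarray  # (n_coils, H, W) complex

    def forward(self, x: np.ndarray) -> np.ndarray:
        return fft2c(self.maps * x[None])

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return (np.conj(self.maps) * ifft2c(y)).sum(axis=0)

    def dc_solve_cg(
        self, z: np.ndarray, b: np.ndarray, mask: SamplingMask, lam: float,
        cg_tol: float = 1e-12,
    ) -> np.ndarray:
        """argmin_x ||M A x - b||^2 + lam ||x - z||^2 with A the coil-
        weighted DFT; solved by CG on the normal equations."""
        n_coils, H, W = self.maps.shape
        m = mask.line_kept.astype(float)[None, None, :]

        def matvec(xflat):
            x = xflat.reshape(H, W)
            return (self.adjoint(m * self.forward(x)) + lam * x).ravel()

        A = LinearOperator((H * W, H * W), matvec=matvec, dtype=np.complex128)
        rhs = (self.adjoint(m * b) + lam * z).ravel()
        sol, info = cg(A, rhs, rtol=cg_tol, maxiter=500)
        if info != 0:
            raise RuntimeError(f"CG did not converge (info={info})")
        return sol.reshape(H, W)


class UnrolledNet:
    """Trainable unrolled model: a shared regularizer network plus a
    trainable DC weight, differentiable end to end.

    The acquisition mask is recovered from the (masked) input k-space as
    the set of columns with any nonzero entry — exact for simulated
    undersampled data, where dropped lines are identically zero.
    """

    def __init__(self, net, cfg: UnrolledConfig):
        from .autograd import Parameter

        self.net = net
        self.cfg = cfg
        self.dc_lambda = Parameter(float(cfg.dc_lambda), "unrolled.dc_lambda")

    def parameters(self):
        return self.net.parameters() + [self.dc_lambda]

    def apply(self, u0, training: bool = False):
        from . import autograd as ag
        from .autograd import as_tensor
        from .networks import apply_network

        u0 = as_tensor(u0)
        b = u0.data[..., 0] + 1j * u0.data[..., 1]  # (B, H, W) acquired k-space
        masks = np.abs(b).sum(axis=1) > 0  # (B, W) kept-line indicator
        lam = ag.clamp_min(self.dc_lambda, 1e-6)
        x = ag.ifft_pairs(u0)
        for _ in range(self.cfg.K):
            _, z = apply_network(self.net, ag.fft_pairs(x), training=training)
            x = _dc_apply_tensor(z, b, masks, lam)
        return ag.fft_pairs(x), x


def _dc_apply_tensor(z, b: np.ndarray, masks: np.ndarray, lam):
    """Differentiable closed-form DC update on (B, H, W, 2) tensors.

    Gradients: the update is real-linear and self-adjoint in z (diagonal
    in k-space with real weights lam/(M+lam)), so the z-gradient applies
    the same filter to the incoming gradient; the lam-gradient follows
    from differentiating the per-coefficient quotient.
    """
    from .autograd import Tensor

    m = masks[:, None, :].astype(float)  # (B, 1, W) broadcast over k_x
    lam_v = float(lam.data)
    fz = fft2c(z.data[..., 0] + 1j * z.data[..., 1])
    num = m * b + lam_v * fz
    out_c = ifft2c(num / (m + lam_v))
    out_data = np.stack([out_c.real, out_c.imag], axis=-1)

    def backward(g):
        gc = g[..., 0] + 1j * g[..., 1]
        if z.requires_grad:
            d = lam_v / (m + lam_v)
            dz_c = ifft2c(d * fft2c(gc))
            z._accumulate(np.stack([dz_c.real, dz_c.imag], axis=-1))
        if lam.requires_grad:
            dout_dlam = ifft2c(m * (fz - b) / (m + lam_v) ** 2)
            lam._accumulate(
                np.array(np.sum(gc.real * dout_dlam.real + gc.imag * dout_dlam.imag))
            )

    return Tensor(out_data, parents=(z, lam), backward=backward)


def unrolled_forward(
    cfg: UnrolledConfig,
    regularizer: Callable[[np.ndarray], np.ndarray],
    b: ComplexGrid | np.ndarray,
    mask: SamplingMask,
    return_internals: bool = False,
):
    """K iterations of (regularizer, analytical DC update).

    The iterate starts from the zero-filled reconstruction of the masked
    acquisition.  ``regularizer`` maps a complex image array to a complex
    image array; a :class:`~jointmri.networks.ReconNetwork` may be passed
    directly (its k-space input is the DFT of the iterate).  With
    ``share_weights`` (the default) the same regularizer is applied at
    every iteration, mirroring the weight-sharing convention of unrolled
    optimization networks.
    """
    from .networks import ReconNetwork, forward as net_forward

    bv = _values(b, KSPACE)
    m = mask.line_kept[None, :]
    x = ifft2c(bv * m)

    if isinstance(regularizer, ReconNetwork):
        net = regularizer

        def regularizer(img: np.ndarray) -> np.ndarray:
            _, i_hat = net_forward(net, ComplexGrid(fft2c(img), KSPACE))
            return i_hat.values

    z = None
    for _ in range(cfg.K):
        z = regularizer(x)
        x = dc_solve(z, bv, mask, cfg.dc_lambda, solver=cfg.dc_solver).values
    if return_internals:
        return ComplexGrid(x, IMAGE), {"last_regularizer_output": z}
    return ComplexGrid(x, IMAGE)
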