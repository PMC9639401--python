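"""Minimal reverse-mode autodiff on NumPy arrays.

The package's networks are small enough that a purpose-built tape — a
:class:`Tensor` wrapping an ``ndarray`` plus the handful of operations the
joint layers actually use — is simpler and easier to audit than a general
framework.  Gradients for every op are hand-derived; the centered
orthonormal DFT is unitary, so its real-linear Jacobian is orthogonal and
backpropagation through it applies the inverse transform to the incoming
gradient.

Array layout convention for network features: ``(B, H, W, C)`` with complex
planes stored as interleaved real channel pairs (see :mod:`.fourier`).
"""

from __future__ import annotations

import numpy as np

from .fourier import fft2c, ifft2c

__all__ = ["Tensor", "Parameter", "as_tensor"]


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this node through its ancestors."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable leaf tensor with a hierarchical name."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x) -> Tensor:
    from scipy.special import expit

    x = as_tensor(x)
    out_data = expit(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def square(x) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x._accumulate(2.0 * g * x.data)

    return Tensor(x.data**2, parents=(x,), backward=backward)


def sqrt(x, eps: float = 0.0) -> Tensor:
    x = as_tensor(x)
    out_data = np.sqrt(x.data + eps)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / out_data)

    return Tensor(out_data, parents=(x,), backward=backward)


def absolute(x) -> Tensor:
    """|x| with the subgradient 0 at the origin."""
    x = as_tensor(x)
    s = np.sign(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s)

    return Tensor(np.abs(x.data), parents=(x,), backward=backward)


def log(x) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=backward)


def pow_const(x, p: float) -> Tensor:
    """x ** p for a fixed exponent, x > 0."""
    x = as_tensor(x)
    out_data = x.data**p

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * p * x.data ** (p - 1.0))

    return Tensor(out_data, parents=(x,), backward=backward)


def clamp_min(x, lo: float) -> Tensor:
    x = as_tensor(x)
    mask = x.data > lo

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(np.where(mask, x.data, lo), parents=(x,), backward=backward)


def mean(x) -> Tensor:
    x = as_tensor(x)
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / n, x.shape).astype(np.float64))

    return Tensor(x.data.mean(), parents=(x,), backward=backward)


def total(x) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.shape).astype(np.float64))

    return Tensor(x.data.sum(), parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_spatial(x: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    np_mode = "wrap" if mode == "periodic" else "constant"
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)), mode=np_mode)


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, Hp, Wp, C) -> (B, H, W, kh*kw*C) sliding windows (stride 1)."""
    from numpy.lib.stride_tricks import sliding_window_view

    B, Hp, Wp, C = xp.shape
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (B, H, W, C, kh, kw)
    v = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    return v.reshape(B, Hp - kh + 1, Wp - kw + 1, kh * kw * C)


def _conv_raw(x: np.ndarray, w: np.ndarray, pad_mode: str):
    """Raw 'same' cross-correlation; returns (output, im2col columns)."""
    kh, kw, cin, cout = w.shape
    xp = _pad_spatial(x, kh // 2, kw // 2, pad_mode)
    cols = _im2col(xp, kh, kw)
    B, H, W, _ = cols.shape
    out = cols.reshape(-1, kh * kw * cin) @ w.reshape(kh * kw * cin, cout)
    return out.reshape(B, H, W, cout), cols


def conv2d(x, w, b, pad_mode: str = "zeros") -> Tensor:
    """'Same'-size stride-1 2D cross-correlation.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).
    ``pad_mode`` is ``"zeros"`` (default) or ``"periodic"``.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    kh, kw, cin, cout = w.shape
    if x.shape[-1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]} channels, kernel expects {cin}"
        )
    out_data, cols = _conv_raw(x.data, w.data, pad_mode)
    out_data = out_data + b.data

    def backward(g):
        g2 = g.reshape(-1, cout)
        if w.requires_grad:
            dw = cols.reshape(-1, kh * kw * cin).T @ g2
            w._accumulate(dw.reshape(kh, kw, cin, cout))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            # input gradient == 'same' correlation of g with the spatially
            # flipped kernel, in/out channels swapped (same padding mode)
            wf = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            dx, _ = _conv_raw(g, np.ascontiguousarray(wf), pad_mode)
            x._accumulate(dx)

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def filter2d_valid(x, kernel: np.ndarray) -> Tensor:
    """Valid-mode cross-correlation of a 2D tensor with a fixed kernel.

    Used by the differentiable SSIM loss; the kernel carries no gradient.
    """
    from scipy.signal import convolve2d

    x = as_tensor(x)
    kernel = np.asarray(kernel, dtype=np.float64)
    out_data = convolve2d(x.data, kernel[::-1, ::-1], mode="valid")

    def backward(g):
        if x.requires_grad:
            x._accumulate(convolve2d(g, kernel, mode="full"))

    return Tensor(out_data, parents=(x,), backward=backward)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling on a 2D tensor (truncating odd edges)."""
    x = as_tensor(x)
    H, W = x.shape
    H2, W2 = H // 2, W // 2
    v = x.data[: 2 * H2, : 2 * W2].reshape(H2, 2, W2, 2)
    out_data = v.mean(axis=(1, 3))

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[: 2 * H2, : 2 * W2] = np.repeat(np.repeat(g, 2, axis=0), 2, axis=1) / 4.0
            x._accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# Fourier ops on interleaved channel pairs
# ---------------------------------------------------------------------------

def _pairs_to_complex(v: np.ndarray) -> np.ndarray:
    return v[..., 0::2] + 1j * v[..., 1::2]


def _complex_to_pairs(c: np.ndarray) -> np.ndarray:
    out = np.empty(c.shape[:-1] + (2 * c.shape[-1],), dtype=np.float64)
    out[..., 0::2] = c.real
    out[..., 1::2] = c.imag
    return out


def _apply_pairwise(v: np.ndarray, transform) -> np.ndarray:
    # v: (B, H, W, C) with C even; transform acts on axes (1, 2)
    return _complex_to_pairs(transform(_pairs_to_complex(v), axes=(1, 2)))


def fft_pairs(x) -> Tensor:
    """Centered orthonormal DFT applied to each (re, im) channel pair.

    The transform is unitary, so the backward pass is the inverse DFT.
    """
    x = as_tensor(x)
    out_data = _apply_pairwise(x.data, fft2c)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_apply_pairwise(g, ifft2c))

    return Tensor(out_data, parents=(x,), backward=backward)


def ifft_pairs(x) -> Tensor:
    """Inverse of :func:`fft_pairs`; backward applies the forward DFT."""
    x = as_tensor(x)
    out_data = _apply_pairwise(x.data, ifft2c)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_apply_pairwise(g, fft2c))

    return Tensor(out_data, parents=(x,), backward=backward)


def tile_pairs(x, n: int) -> Tensor:
    """Tile a (B, H, W, 2) residual across n complex channel pairs."""
    x = as_tensor(x)
    out_data = np.tile(x.data, (1, 1, 1, n))

    def backward(g):
        if x.requires_grad:
            B, H, W, C = g.shape
            x._accumulate(g.reshape(B, H, W, n, C // n).sum(axis=3))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(
    x,
    gamma,
    beta,
    state: dict,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (batch, height, width).

    ``state`` holds ``running_mean`` / ``running_var`` numpy arrays, updated
    in place in training mode and consumed in inference mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        state["running_mean"] = momentum * state["running_mean"] + (1 - momentum) * mu
        state["running_var"] = momentum * state["running_var"] + (1 - momentum) * var
    else:
        mu = state["running_mean"]
        var = state["running_var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            if training:
                n = g.shape[0] * g.shape[1] * g.shape[2]
                dxhat = g * gamma.data
                dx = (
                    inv_std
                    / n
                    * (
                        n * dxhat
                        - dxhat.sum(axis=(0, 1, 2))
                        - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
                    )
                )
            else:
                dx = g * gamma.data * inv_std
            x._accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)
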