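"""Differentiable SSIM / MS-SSIM on the autodiff tape.

Mirrors the reference SSIM formulation (11×11 Gaussian window, sigma 1.5,
K1 = 0.01, K2 = 0.03, population covariances, mean over the valid region)
so that the loss value matches the skimage metric; the window shrinks to
the largest odd size that fits when images are small.  MS-SSIM uses the
standard 5-scale weighting, truncated and renormalized when the image is
too small for all five scales; the per-scale contrast-structure terms are
clamped at a small positive floor so fractional powers stay defined.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d

from . import autograd as ag
from .autograd import Tensor, as_tensor

K1, K2 = 0.01, 0.03
MS_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])

__all__ = ["gaussian_kernel", "ssim_tensor", "ms_ssim_tensor", "ssim_win_size"]


def ssim_win_size(h: int, w: int, win: int = 11) -> int:
    m = min(h, w, win)
    return m if m % 2 == 1 else m - 1


def gaussian_kernel(win: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = (win - 1) // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def _filt_const(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return convolve2d(y, kernel[::-1, ::-1], mode="valid")


def _ssim_maps(x: Tensor, y: np.ndarray, data_range: float, win: int, sigma: float):
    """Return (ssim_map, cs_map) tensors for one 2D magnitude pair."""
    kernel = gaussian_kernel(win, sigma)
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    ux = ag.filter2d_valid(x, kernel)
    uy = _filt_const(y, kernel)
    uxx = ag.filter2d_valid(ag.square(x), kernel)
    uyy = _filt_const(y * y, kernel)
    uxy = ag.filter2d_valid(x * Tensor(y), kernel)
    vx = uxx - ag.square(ux)
    vy = uyy - uy**2
    vxy = uxy - ux * uy
    lum = (2.0 * uy * ux + c1) / (ag.square(ux) + (uy**2 + c1))
    cs = (2.0 * vxy + c2) / (vx + (vy + c2))
    return lum * cs, cs


def ssim_tensor(
    x, y: np.ndarray, data_range: float, win: int = 11, sigma: float = 1.5
) -> Tensor:
    """Mean SSIM between a differentiable magnitude image ``x`` and a
    fixed reference ``y`` (both 2D, nonnegative)."""
    x = as_tensor(x)
    h, w = x.shape
    win = ssim_win_size(h, w, win)
    smap, _ = _ssim_maps(x, np.asarray(y, dtype=np.float64), data_range, win, sigma)
    return ag.mean(smap)


def ms_ssim_tensor(
    x, y: np.ndarray, data_range: float, win: int = 11, sigma: float = 1.5
) -> Tensor:
    """Multiscale SSIM with the standard 5-scale weights.

    The number of scales is reduced (weights renormalized) when the image
    cannot support five rounds of halving with the SSIM window.
    """
    x = as_tensor(x)
    y = np.asarray(y, dtype=np.float64)
    h, w = x.shape
    win = ssim_win_size(h, w)
    n_scales = 1
    d = min(h, w)
    while n_scales < len(MS_WEIGHTS) and d // 2 >= win:
        n_scales += 1
        d //= 2
    weights = MS_WEIGHTS[:n_scales] / MS_WEIGHTS[:n_scales].sum()
    out: Tensor | None = None
    for scale in range(n_scales):
        last = scale == n_scales - 1
        smap, cs_map = _ssim_maps(x, y, data_range, win, sigma)
        term = ag.mean(smap) if last else ag.mean(cs_map)
        factor = ag.pow_const(ag.clamp_min(term, 1e-6), float(weights[scale]))
        out = factor if out is None else out * factor
        if not last:
            x = ag.avg_pool2(x)
            hy, wy = y.shape
            y = y[: 2 * (hy // 2), : 2 * (wy // 2)].reshape(hy // 2, 2, wy // 2, 2).mean(axis=(1, 3))
    return out
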