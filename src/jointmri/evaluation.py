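"""Reconstruction quality metrics and diagnostics.

SSIM and PSNR go through scikit-image with the standard settings (11×11
Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03); the data range defaults
to the maximum magnitude of the ground-truth image.  Multiscale SSIM uses
the package's own implementation (standard 5-scale weighting).  The
correlation-map diagnostic visualizes how strongly a single anchor pixel
co-varies with every other pixel across a dataset, separately for the
image and k-space magnitude representations — in k-space these maps are
conjugate-symmetric for real-valued image datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .autograd import Tensor
from .fourier import ComplexGrid, fft2c
from .ssim import ms_ssim_tensor, ssim_win_size
from .training import compute_loss

PSNR_CAP = 300.0  # dB sentinel for identical image pairs

__all__ = [
    "ssim",
    "psnr",
    "ms_ssim",
    "MetricsReport",
    "evaluate_dataset",
    "correlation_map",
    "CorrelationMaps",
    "PSNR_CAP",
]


def _mag(x) -> np.ndarray:
    if isinstance(x, ComplexGrid):
        return x.magnitude
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else x.astype(np.float64)


def ssim(a, b, data_range: float | None = None) -> float:
    """SSIM between magnitude images (``b`` is the ground truth; the data
    range defaults to its maximum)."""
    a, b = _mag(a), _mag(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = max(float(b.max()), 1e-12)
    win = ssim_win_size(*a.shape)
    return float(
        structural_similarity(
            a,
            b,
            win_size=win,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def psnr(a, b, data_range: float | None = None) -> float:
    """PSNR in dB; identical pairs report the finite cap ``PSNR_CAP``."""
    a, b = _mag(a), _mag(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = max(float(b.max()), 1e-12)
    if np.array_equal(a, b):
        return PSNR_CAP
    return float(peak_signal_noise_ratio(b, a, data_range=data_range))


def ms_ssim(a, b, data_range: float | None = None) -> float:
    """Multiscale SSIM of magnitude images (5-scale standard weighting,
    truncated on small images)."""
    a, b = _mag(a), _mag(b)
    if data_range is None:
        data_range = max(float(b.max()), 1e-12)
    return ms_ssim_tensor(Tensor(a), b, data_range).item()


@dataclass
class MetricsReport:
    """Per-slice metric records plus mean ± sd aggregates."""

    per_slice: list[dict]
    aggregate: dict[str, tuple[float, float]]

    def mean(self, metric: str) -> float:
        return self.aggregate[metric][0]


_METRICS = ("freq_l1", "image_l1", "joint_l1", "ssim", "ms_ssim", "psnr")


def evaluate_dataset(recons, targets) -> MetricsReport:
    """Score paired reconstructions and targets (sequences of complex
    slices or ComplexGrids) with the full metric battery."""
    recons = [r.values if isinstance(r, ComplexGrid) else np.asarray(r) for r in recons]
    targets = [t.values if isinstance(t, ComplexGrid) else np.asarray(t) for t in targets]
    if len(recons) == 0:
        raise ValueError("empty dataset")
    if len(recons) != len(targets):
        raise ValueError("reconstruction/target count mismatch")
    per_slice = []
    for r, t in zip(recons, targets):
        rec = {
            "freq_l1": compute_loss("freq_l1", r, t),
            "image_l1": compute_loss("image_l1", r, t),
            "joint_l1": compute_loss("joint_l1", r, t),
            "ssim": ssim(np.abs(r), np.abs(t)),
            "ms_ssim": ms_ssim(np.abs(r), np.abs(t)),
            "psnr": psnr(np.abs(r), np.abs(t)),
        }
        per_slice.append(rec)
    aggregate = {
        m: (
            float(np.mean([s[m] for s in per_slice])),
            float(np.std([s[m] for s in per_slice])),
        )
        for m in _METRICS
    }
    return MetricsReport(per_slice=per_slice, aggregate=aggregate)


def rank_subjects(scores: dict[str, list[float]], by: str) -> np.ndarray:
    """Subject ordering sorted by one method's per-subject score
    (presentation helper for side-by-side method comparisons)."""
    return np.argsort(np.asarray(scores[by]))


@dataclass
class CorrelationMaps:
    """Pearson correlation of one anchor pixel with all pixels, across a
    dataset, for the image and k-space magnitude representations."""

    image: np.ndarray
    kspace: np.ndarray
    anchor: tuple[int, int]


def correlation_map(dataset, anchor: tuple[int, int]) -> CorrelationMaps:
    """Correlation between the anchor entry and every entry across slices.

    ``dataset`` is a sequence of image-space complex slices (≥ 3).  Pixels
    with zero variance (including a degenerate anchor) yield NaN.
    """
    slices = [
        s.values if isinstance(s, ComplexGrid) else np.asarray(s, dtype=np.complex128)
        for s in dataset
    ]
    if len(slices) < 3:
        raise ValueError("correlation maps need at least 3 slices")
    img = np.abs(np.stack(slices))
    ksp = np.abs(np.stack([fft2c(s) for s in slices]))

    def corr(stack: np.ndarray) -> np.ndarray:
        n = stack.shape[0]
        a = stack[:, anchor[0], anchor[1]]
        az = a - a.mean()
        sz = stack - stack.mean(axis=0)
        cov = (az[:, None, None] * sz).sum(axis=0) / n
        a_sd = np.sqrt((az**2).sum() / n)
        s_sd = np.sqrt((sz**2).sum(axis=0) / n)
        # zero-variance pixels (up to fp roundoff of the mean) are undefined
        tol = 1e-10 * (np.abs(stack).max() + 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cov / (a_sd * s_sd)
        out[(s_sd < tol)] = np.nan
        if a_sd < tol:
            out[:] = np.nan
        return out

    return CorrelationMaps(image=corr(img), kspace=corr(ksp), anchor=tuple(anchor))
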