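"""Synthetic complex-valued phantoms and task datasets.

The generator superposes randomly placed ellipses (anatomical-like piecewise
constant structure, zero background) and applies a smooth low-order
polynomial phase so the images are genuinely complex — this exercises the
conjugate-asymmetric code paths that magnitude-only data would never touch.
A ``real`` flag reproduces the real-image regime, whose k-space is exactly
Hermitian-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corruption import CorruptionConfig, simulate_task
from .fourier import IMAGE, ComplexGrid, fft2c, grid_to_channels

__all__ = ["PhantomSpec", "generate_phantom", "make_dataset_arrays", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Phantom geometry and texture parameters.

    size
        Grid side length N (64 by default: desk-scale training resolution).
    n_ellipses
        Inclusive range for the number of superposed ellipses.
    intensity
        Range of per-ellipse additive intensities; the summed magnitude is
        rescaled to peak at 1.
    phase_scale
        Scale (radians) of the random low-order polynomial phase.
    real
        If true, the phase is zero and the phantom is real-valued.
    """

    size: int = 64
    n_ellipses: tuple[int, int] = (5, 12)
    intensity: tuple[float, float] = (0.2, 1.0)
    phase_scale: float = 1.5
    real: bool = False

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("size must be at least 16")


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> ComplexGrid:
    """Draw one phantom: overlapping ellipses, magnitude in [0, 1], smooth
    polynomial phase, zero background."""
    n = spec.size
    yy, xx = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    mag = np.zeros((n, n))
    n_ell = int(rng.integers(spec.n_ellipses[0], spec.n_ellipses[1] + 1))
    for _ in range(n_ell):
        cx, cy = rng.uniform(-0.45, 0.45, 2)
        a, b = rng.uniform(0.08, 0.5, 2)
        theta = rng.uniform(0, np.pi)
        inten = rng.uniform(*spec.intensity)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        mag += inten * (((xr / a) ** 2 + (yr / b) ** 2) <= 1.0)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    if spec.real:
        return ComplexGrid(mag.astype(np.complex128), IMAGE)
    # smooth low-order polynomial phase, only meaningful where mag > 0
    c = rng.uniform(-spec.phase_scale, spec.phase_scale, 6)
    phase = c[0] + c[1] * xx + c[2] * yy + c[3] * xx * yy + c[4] * xx**2 + c[5] * yy**2
    return ComplexGrid(mag * np.exp(1j * phase), IMAGE)


def make_dataset_arrays(
    n: int,
    phantom_spec: PhantomSpec,
    corruption_cfg: CorruptionConfig,
    seed: int,
) -> dict:
    """Generate n (corrupted k-space, target image[, mask]) triples as
    arrays, plus leakage-free train/val/test split indices (70/15/15)."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    size = phantom_spec.size
    kspace = np.empty((n, size, size, 2))
    target = np.empty((n, size, size, 2))
    masks = np.empty((n, size), dtype=bool)
    has_mask = False
    for i in range(n):
        phantom = generate_phantom(phantom_spec, rng)
        corrupted, tgt, mask = simulate_task(phantom, corruption_cfg, rng)
        kspace[i] = grid_to_channels(corrupted.values)
        target[i] = grid_to_channels(tgt.values)
        if mask is not None:
            has_mask = True
            masks[i] = mask.line_kept
    n_train = int(round(0.7 * n))
    n_val = int(round(0.15 * n))
    idx = np.arange(n)
    out = {
        "kspace_corrupted": kspace,
        "image_target": target,
        "split_train": idx[:n_train],
        "split_val": idx[n_train : n_train + n_val],
        "split_test": idx[n_train + n_val :],
        "config": corruption_cfg,
        "seed": seed,
    }
    if has_mask:
        out["mask"] = masks
    return out


def generate_dataset(
    n: int,
    phantom_spec: PhantomSpec,
    corruption_cfg: CorruptionConfig,
    seed: int,
    path,
) -> None:
    """Generate a dataset and write it to an HDF5 file (see :mod:`.io`)."""
    from .io import write_hdf5_dataset

    data = make_dataset_arrays(n, phantom_spec, corruption_cfg, seed)
    write_hdf5_dataset(path, data)
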