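"""Simulators for the three k-space acquisition corruptions.

A Cartesian 2D acquisition reads one k-space column ("k_y line") at a
time, so the natural corruption unit is the line:

* **rigid motion** — the subject's pose is piecewise constant over line
  acquisitions; each line of the corrupted k-space is the corresponding
  line of the DFT of the rigidly transformed image;
* **complex Gaussian noise** — i.i.d. noise added to every k-space sample
  (giving the usual Rician magnitude statistics);
* **undersampling** — a subset of lines is acquired and the rest zeroed.

All randomness flows through an explicit ``numpy`` Generator, so every
corruption is reproducible from a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .fourier import IMAGE, KSPACE, ComplexGrid, fft2c, ifft2c, to_image, to_kspace

TASKS = ("motion", "noise", "undersample", "motion+undersample")
MASK_SCHEMES = (
    "random",
    "equispaced_4x_center8",
    "equispaced_8x_center4",
    "motion_combo_4x",
)

__all__ = [
    "CorruptionConfig",
    "MotionTrajectory",
    "SamplingMask",
    "sample_motion_trajectory",
    "apply_rigid_transform",
    "simulate_motion_corruption",
    "translation_phase_ramp",
    "rotation_in_kspace",
    "add_complex_gaussian_noise",
    "make_sampling_mask",
    "apply_mask",
    "simulate_task",
    "TASKS",
    "MASK_SCHEMES",
]


@dataclass
class CorruptionConfig:
    """Knobs for one corruption task.

    gamma_m is the fraction of lines at which a new motion state is drawn
    (0.03 by default); translations are uniform on ±trans_range pixels and
    rotations uniform on ±rot_range degrees — deliberately extreme motion.
    noise_sigma is the per-component k-space noise standard deviation in
    (normalized) signal units; gamma_s the fraction of lines kept by the
    random undersampling scheme (0.25 = 4x acceleration).
    """

    task: str = "undersample"
    gamma_m: float = 0.03
    trans_range: float = 8.0
    rot_range: float = 11.0
    noise_sigma: float = 0.25
    gamma_s: float = 0.25
    mask_scheme: str = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if not (0.0 <= self.gamma_m <= 1.0):
            raise ValueError("gamma_m must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.mask_scheme not in MASK_SCHEMES:
            raise ValueError(f"unknown mask scheme {self.mask_scheme!r}")


@dataclass
class MotionTrajectory:
    """Piecewise-constant per-line rigid motion parameters.

    ``per_line`` has one (dx, dy, phi_degrees) row per k_y line; the state
    changes only at ``change_lines`` and is the identity before the first
    change, so the target image keeps the reference pose.
    """

    per_line: np.ndarray  # (n_lines, 3)
    change_lines: np.ndarray  # sorted k_y indices

    @property
    def n_lines(self) -> int:
        return self.per_line.shape[0]


@dataclass
class SamplingMask:
    """Per-k_y-line acquisition indicator plus scheme metadata."""

    line_kept: np.ndarray  # (W,) bool
    scheme: str
    center_fraction: float = 0.0
    acceleration: float = 0.0

    @property
    def n_kept(self) -> int:
        return int(self.line_kept.sum())


def sample_motion_trajectory(
    n_lines: int, cfg: CorruptionConfig, rng: np.random.Generator
) -> MotionTrajectory:
    """Draw a piecewise-constant trajectory with ceil(gamma_m * n_lines)
    change points placed uniformly without replacement."""
    if n_lines < 1:
        raise ValueError("n_lines must be positive")
    per_line = np.zeros((n_lines, 3))
    expected = cfg.gamma_m * n_lines
    if expected == 0:
        return MotionTrajectory(per_line, np.array([], dtype=int))
    if expected < 1:
        warnings.warn(
            "gamma_m * n_lines < 1: no motion change points generated "
            "(identity trajectory)",
            stacklevel=2,
        )
        return MotionTrajectory(per_line, np.array([], dtype=int))
    n_change = int(np.ceil(expected))
    change_lines = np.sort(rng.choice(n_lines, size=n_change, replace=False))
    params = np.column_stack(
        [
            rng.uniform(-cfg.trans_range, cfg.trans_range, n_change),
            rng.uniform(-cfg.trans_range, cfg.trans_range, n_change),
            rng.uniform(-cfg.rot_range, cfg.rot_range, n_change),
        ]
    )
    # each state holds from its change line (inclusive) to the next (exclusive)
    for i, start in enumerate(change_lines):
        stop = change_lines[i + 1] if i + 1 < n_change else n_lines
        per_line[start:stop] = params[i]
    return MotionTrajectory(per_line, change_lines)


def apply_rigid_transform(
    img: ComplexGrid | np.ndarray,
    dx: float,
    dy: float,
    phi: float,
    wrap: bool = False,
) -> ComplexGrid:
    """Rigidly transform an image: translate by (dx, dy) pixels, rotate by
    phi degrees about the image center pixel (H//2, W//2).

    The output at (x, y) samples the input at the translated-then-rotated
    source coordinates with bilinear interpolation; out-of-frame samples
    are zero (or wrap around with ``wrap=True``, the circular-shift
    convention used by the phase-ramp oracle).
    """
    arr = img.values if isinstance(img, ComplexGrid) else np.asarray(img, dtype=np.complex128)
    if dx == 0.0 and dy == 0.0 and phi == 0.0:
        return ComplexGrid(arr.copy(), IMAGE)
    H, W = arr.shape
    cx, cy = H // 2, W // 2
    x, y = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    xr = x - cx - dx
    yr = y - cy - dy
    rad = np.deg2rad(phi)
    c, s = np.cos(rad), np.sin(rad)
    src_x = xr * c - yr * s + cx
    src_y = xr * s + yr * c + cy
    mode = "grid-wrap" if wrap else "constant"
    out = (
        map_coordinates(arr.real, [src_x, src_y], order=1, mode=mode, cval=0.0)
        + 1j * map_coordinates(arr.imag, [src_x, src_y], order=1, mode=mode, cval=0.0)
    )
    return ComplexGrid(out, IMAGE)


def simulate_motion_corruption(
    img: ComplexGrid | np.ndarray, traj: MotionTrajectory, wrap: bool = False
) -> ComplexGrid:
    """Assemble motion-corrupted k-space line by line.

    Column k_y of the output is column k_y of the DFT of the image in the
    pose held while that line was acquired.  One transform + DFT is
    computed per distinct motion state, not per line.
    """
    arr = img.values if isinstance(img, ComplexGrid) else np.asarray(img, dtype=np.complex128)
    H, W = arr.shape
    if traj.n_lines != W:
        raise ValueError(
            f"trajectory covers {traj.n_lines} lines but the grid has {W} columns"
        )
    out = np.empty((H, W), dtype=np.complex128)
    states, inverse = np.unique(traj.per_line, axis=0, return_inverse=True)
    for si, state in enumerate(states):
        cols = np.nonzero(inverse == si)[0]
        transformed = apply_rigid_transform(arr, *state, wrap=wrap)
        k = fft2c(transformed.values)
        out[:, cols] = k[:, cols]
    return ComplexGrid(out, KSPACE)


def translation_phase_ramp(
    ksp: ComplexGrid | np.ndarray, dx: float, dy: float
) -> ComplexGrid:
    """Fourier shift theorem: multiply k-space by the linear phase ramp
    exp(-j 2π (k_x dx / H + k_y dy / W)) with centered k indices."""
    arr = ksp.values if isinstance(ksp, ComplexGrid) else np.asarray(ksp, dtype=np.complex128)
    H, W = arr.shape
    kx = (np.arange(H) - H // 2)[:, None]
    ky = (np.arange(W) - W // 2)[None, :]
    ramp = np.exp(-2j * np.pi * (kx * dx / H + ky * dy / W))
    return ComplexGrid(arr * ramp, KSPACE)


def rotation_in_kspace(ksp: ComplexGrid | np.ndarray, phi: float) -> ComplexGrid:
    """Fourier rotation theorem oracle: resample k-space on coordinates
    rotated by phi degrees about the DC center (bilinear, zero fill).

    Diagnostic counterpart of image-space rotation; not used in the main
    simulation path.
    """
    arr = ksp.values if isinstance(ksp, ComplexGrid) else np.asarray(ksp, dtype=np.complex128)
    rotated = apply_rigid_transform(arr, 0.0, 0.0, phi)
    return ComplexGrid(rotated.values, KSPACE)


def add_complex_gaussian_noise(
    ksp: ComplexGrid | np.ndarray, sigma: float, rng: np.random.Generator
) -> ComplexGrid:
    """Add i.i.d. eps1 + j*eps2 with eps1, eps2 ~ N(0, sigma^2) per entry."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    arr = ksp.values if isinstance(ksp, ComplexGrid) else np.asarray(ksp, dtype=np.complex128)
    if sigma == 0:
        return ComplexGrid(arr.copy(), KSPACE)
    noise = rng.normal(0.0, sigma, arr.shape) + 1j * rng.normal(0.0, sigma, arr.shape)
    return ComplexGrid(arr + noise, KSPACE)


def _even_center_count(frac: float, width: int) -> int:
    # symmetric band about DC: round the center count to the nearest even
    return 2 * int(round(frac * width / 2.0))


def make_sampling_mask(
    width: int,
    scheme: str,
    rng: np.random.Generator | None = None,
    gamma_s: float = 0.25,
) -> SamplingMask:
    """Build a per-line sampling mask for one of the supported schemes.

    random
        keeps floor(gamma_s * width) lines uniformly at random, with no
        bias toward the low-frequency center.
    equispaced_4x_center8 / equispaced_8x_center4
        keep a contiguous central band (8% / 4% of lines, rounded to an
        even count so the band is symmetric about DC) plus every 4th / 8th
        outer line.
    motion_combo_4x
        keeps the full central 8% band plus uniformly random outer lines
        to reach 25% of lines kept overall.
    """
    if width < 8:
        raise ValueError("width must be at least 8")
    kept = np.zeros(width, dtype=bool)
    if scheme == "random":
        if rng is None:
            raise ValueError("the random scheme requires an rng")
        n_keep = int(gamma_s * width)
        kept[rng.choice(width, size=n_keep, replace=False)] = True
        return SamplingMask(kept, scheme, center_fraction=0.0, acceleration=1.0 / gamma_s)
    if scheme in ("equispaced_4x_center8", "equispaced_8x_center4"):
        frac, step = (0.08, 4) if scheme.endswith("4x_center8") else (0.04, 8)
        n_c = _even_center_count(frac, width)
        lo = width // 2 - n_c // 2
        kept[lo : lo + n_c] = True
        kept[::step] = True
        return SamplingMask(kept, scheme, center_fraction=frac, acceleration=float(step))
    if scheme == "motion_combo_4x":
        if rng is None:
            raise ValueError("motion_combo_4x requires an rng")
        n_c = _even_center_count(0.08, width)
        lo = width // 2 - n_c // 2
        kept[lo : lo + n_c] = True
        n_total = int(round(0.25 * width))
        outer = np.setdiff1d(np.arange(width), np.arange(lo, lo + n_c))
        n_outer = max(n_total - n_c, 0)
        kept[rng.choice(outer, size=n_outer, replace=False)] = True
        return SamplingMask(kept, scheme, center_fraction=0.08, acceleration=4.0)
    raise ValueError(f"unknown mask scheme {scheme!r}")


def apply_mask(ksp: ComplexGrid | np.ndarray, mask: SamplingMask) -> ComplexGrid:
    """Zero the non-acquired k_y lines; kept lines are copied verbatim."""
    arr = ksp.values if isinstance(ksp, ComplexGrid) else np.asarray(ksp, dtype=np.complex128)
    if arr.shape[1] != mask.line_kept.shape[0]:
        raise ValueError(
            f"mask covers {mask.line_kept.shape[0]} lines but grid has {arr.shape[1]} columns"
        )
    return ComplexGrid(arr * mask.line_kept[None, :], KSPACE)


def simulate_task(
    img: ComplexGrid | np.ndarray,
    cfg: CorruptionConfig,
    rng: np.random.Generator,
) -> tuple[ComplexGrid, ComplexGrid, SamplingMask | None]:
    """Compose the corruptions for one task and normalize the pair.

    Both the corrupted k-space and the target image are divided by the
    maximum magnitude of the corrupted zero-filled reconstruction, so the
    corrupted image has unit peak magnitude.  The mask is returned for the
    undersampling tasks, ``None`` otherwise.
    """
    arr = img.values if isinstance(img, ComplexGrid) else np.asarray(img, dtype=np.complex128)
    W = arr.shape[1]
    mask: SamplingMask | None = None
    if cfg.task == "motion":
        traj = sample_motion_trajectory(W, cfg, rng)
        corrupted = simulate_motion_corruption(arr, traj).values
    elif cfg.task == "noise":
        corrupted = add_complex_gaussian_noise(fft2c(arr), cfg.noise_sigma, rng).values
    elif cfg.task == "undersample":
        mask = make_sampling_mask(W, cfg.mask_scheme, rng, cfg.gamma_s)
        corrupted = apply_mask(fft2c(arr), mask).values
    else:  # motion+undersample
        traj = sample_motion_trajectory(W, cfg, rng)
        corrupted = simulate_motion_corruption(arr, traj).values
        mask = make_sampling_mask(W, "motion_combo_4x", rng)
        corrupted = apply_mask(corrupted, mask).values
    scale = np.abs(ifft2c(corrupted)).max()
    scale = scale if scale > 0 else 1.0
    return (
        ComplexGrid(corrupted / scale, KSPACE),
        ComplexGrid(arr / scale, IMAGE),
        mask,
    )
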