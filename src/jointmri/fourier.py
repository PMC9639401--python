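"""Discrete Fourier conventions shared by the whole package.

MRI acquires samples of the 2D Fourier transform of a slice ("k-space").
Everything downstream — corruption simulation, the joint layers, data
consistency — depends on one fixed convention for

* scaling: the DFT is orthonormal (``1/sqrt(H*W)`` both directions), so
  Parseval's identity holds exactly and magnitudes are comparable between
  the two spaces;
* centering: the DC coefficient is stored at index ``(H//2, W//2)``, so a
  "central band" of k-space means a contiguous block of array columns;
* channel layout: complex rasters are optionally viewed as real feature
  stacks with channels interleaved ``(re0, im0, re1, im1, ...)``.

These choices are package-wide invariants, not per-call options.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KSPACE = "kspace"
IMAGE = "image"
_SPACES = (KSPACE, IMAGE)

__all__ = [
    "ComplexGrid",
    "FeatureStack",
    "KSPACE",
    "IMAGE",
    "fft2c",
    "ifft2c",
    "to_kspace",
    "to_image",
    "split_complex",
    "join_complex",
    "grid_to_channels",
    "channels_to_grid",
]


@dataclass
class ComplexGrid:
    """An H×W complex raster tagged as living in k-space or image space.

    Parameters
    ----------
    values : ndarray
        2D complex (or real, promoted) array with finite entries.
    space : str
        Either ``"kspace"`` or ``"image"``.  In k-space the DC component
        sits at index ``(H//2, W//2)`` (centered convention).
    """

    values: np.ndarray
    space: str = IMAGE

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"ComplexGrid requires a 2D array, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("ComplexGrid dimensions must be positive")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}, got {self.space!r}")
        v = v.astype(np.complex128, copy=False)
        if not np.all(np.isfinite(v.real)) or not np.all(np.isfinite(v.imag)):
            raise ValueError("ComplexGrid entries must be finite")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class FeatureStack:
    """An H×W×C real feature stack with interleaved (re, im) channel pairs.

    ``C`` must be even; channel ``2i`` holds the real part and ``2i+1`` the
    imaginary part of complex plane ``i``.
    """

    values: np.ndarray
    space: str = IMAGE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"FeatureStack requires an H×W×C array, got {v.shape}")
        if v.shape[2] < 2 or v.shape[2] % 2 != 0:
            raise ValueError(f"channel count must be even and >= 2, got {v.shape[2]}")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}")
        self.values = v

    @property
    def n_pairs(self) -> int:
        return self.values.shape[2] // 2


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal 2D DFT (image -> k-space) on raw arrays."""
    x = np.asarray(x)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered orthonormal inverse 2D DFT (k-space -> image) on raw arrays."""
    x = np.asarray(x)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def to_kspace(img: ComplexGrid | np.ndarray) -> ComplexGrid:
    """Forward transform of an image grid into the centered k-space grid.

    Orthonormal scaling: total energy is preserved (Parseval), and
    ``to_image(to_kspace(x)) == x`` to machine precision.
    """
    if isinstance(img, ComplexGrid):
        if img.space != IMAGE:
            raise ValueError("to_kspace expects an image-space grid")
        arr = img.values
    else:
        arr = np.asarray(img)
        if arr.ndim != 2:
            raise ValueError(f"to_kspace requires a 2D array, got shape {arr.shape}")
    return ComplexGrid(fft2c(arr), KSPACE)


def to_image(ksp: ComplexGrid | np.ndarray) -> ComplexGrid:
    """Exact inverse of :func:`to_kspace` (same centering and scaling)."""
    if isinstance(ksp, ComplexGrid):
        if ksp.space != KSPACE:
            raise ValueError("to_image expects a k-space grid")
        arr = ksp.values
    else:
        arr = np.asarray(ksp)
        if arr.ndim != 2:
            raise ValueError(f"to_image requires a 2D array, got shape {arr.shape}")
    return ComplexGrid(ifft2c(arr), IMAGE)


def split_complex(g: ComplexGrid) -> FeatureStack:
    """View a complex grid as a 2-channel real stack ``(re, im)``."""
    return FeatureStack(np.stack([g.values.real, g.values.imag], axis=-1), g.space)


def join_complex(s: FeatureStack) -> ComplexGrid | list[ComplexGrid]:
    """Rebuild complex grids from interleaved (re, im) channel pairs.

    For ``C == 2`` the round trip through :func:`split_complex` is lossless
    and a single :class:`ComplexGrid` is returned.  For larger even ``C``
    each consecutive channel pair yields one grid and a list is returned.
    """
    v = s.values
    if v.shape[2] % 2 != 0:
        raise ValueError("cannot pair an odd number of channels into complex planes")
    grids = [
        ComplexGrid(v[:, :, 2 * i] + 1j * v[:, :, 2 * i + 1], s.space)
        for i in range(v.shape[2] // 2)
    ]
    return grids[0] if len(grids) == 1 else grids


def grid_to_channels(values: np.ndarray) -> np.ndarray:
    """Raw-array helper: H×W complex -> H×W×2 real (re, im)."""
    values = np.asarray(values, dtype=np.complex128)
    return np.stack([values.real, values.imag], axis=-1)


def channels_to_grid(channels: np.ndarray) -> np.ndarray:
    """Raw-array helper: H×W×2 real -> H×W complex."""
    channels = np.asarray(channels, dtype=np.float64)
    if channels.ndim != 3 or channels.shape[2] != 2:
        raise ValueError(f"expected an H×W×2 array, got {channels.shape}")
    return channels[:, :, 0] + 1j * channels[:, :, 1]
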