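"""Readers and writers for the package's external formats.

HDF5 is the native dataset container (k-space style datasets of paired
arrays); NIfTI volumes can be read as stacks of image slices for real
data.  Arrays are stored as H×W×2 real (re, im) to avoid complex-dtype
portability issues.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .corruption import CorruptionConfig
from .fourier import IMAGE, ComplexGrid

__all__ = [
    "write_hdf5_dataset",
    "read_hdf5_dataset",
    "read_nifti_volume",
    "central_slice_index",
    "save_preview",
]


def write_hdf5_dataset(path, data: dict) -> None:
    """Write a dataset dict (see phantom.make_dataset_arrays) to HDF5.

    Layout: one group per slice holding ``kspace_corrupted`` (H×W×2),
    ``image_target`` (H×W×2) and optionally ``mask`` (W,); file-level
    datasets for the split indices; the corruption config and seed as
    root attributes.
    """
    n = data["kspace_corrupted"].shape[0]
    with h5py.File(path, "w") as f:
        for i in range(n):
            g = f.create_group(f"slice_{i:05d}")
            g.create_dataset("kspace_corrupted", data=data["kspace_corrupted"][i])
            g.create_dataset("image_target", data=data["image_target"][i])
            if "mask" in data:
                g.create_dataset("mask", data=data["mask"][i])
        for split in ("train", "val", "test"):
            f.create_dataset(f"split_{split}", data=np.asarray(data[f"split_{split}"], dtype=np.int64))
        cfg = data.get("config")
        if cfg is not None:
            if dataclasses.is_dataclass(cfg):
                cfg = dataclasses.asdict(cfg)
            f.attrs["config"] = json.dumps(cfg)
        if "seed" in data:
            f.attrs["seed"] = int(data["seed"])


def read_hdf5_dataset(path) -> dict:
    """Read a dataset written by :func:`write_hdf5_dataset` back into
    arrays; the round trip is lossless."""
    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if k.startswith("slice_"))
        if not names:
            raise ValueError(f"{path}: no slice groups found")
        kspace = np.stack([f[name]["kspace_corrupted"][()] for name in names])
        target = np.stack([f[name]["image_target"][()] for name in names])
        out = {"kspace_corrupted": kspace, "image_target": target}
        if "mask" in f[names[0]]:
            out["mask"] = np.stack([f[name]["mask"][()].astype(bool) for name in names])
        for split in ("train", "val", "test"):
            key = f"split_{split}"
            if key in f:
                out[key] = f[key][()]
        if "config" in f.attrs:
            try:
                out["config"] = CorruptionConfig(**json.loads(f.attrs["config"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed 'config' attribute ({exc})") from exc
        if "seed" in f.attrs:
            out["seed"] = int(f.attrs["seed"])
    return out


def read_nifti_volume(path) -> list[ComplexGrid]:
    """Read a NIfTI volume as a list of axial image slices.

    A magnitude-only volume yields grids with zero imaginary part.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(path).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {vol.shape}")
    return [ComplexGrid(vol[:, :, z].astype(np.complex128), IMAGE) for z in range(vol.shape[2])]


def central_slice_index(n_slices: int) -> int:
    return n_slices // 2


def save_preview(path, grid: ComplexGrid) -> None:
    """Write a magnitude preview PNG (uint8, min-max scaled)."""
    import imageio.v3 as iio

    mag = grid.magnitude
    rng = mag.max() - mag.min()
    scaled = (mag - mag.min()) / rng if rng > 0 else np.zeros_like(mag)
    iio.imwrite(path, (255 * scaled).astype(np.uint8))
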