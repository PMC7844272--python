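"""Volume containers and I/O for anisotropic EM image stacks.

Arrays are always indexed ``(z, y, x)`` with 0-based, half-open coordinate
ranges.  The axial (z) sampling of serial block-face SEM data is coarser than
the lateral (y, x) sampling; voxel size metadata records this (default 50 nm
axial, 10 nm lateral).  Grayscale image volumes are floats, segmentations are
small integers over the fixed 7-class platelet schema::

    0 background, 1 cell, 2 mitochondrion, 3 canalicular channel,
    4 alpha granule, 5 dense granule, 6 dense granule core

Supported containers are multi-page TIFF (one page per z-slice) and HDF5
(a single 3D dataset, name configurable, default ``"data"``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

#: The fixed class set C of the labeling schema.
CLASSES = tuple(range(7))
N_CLASSES = 7

#: Organelle class indices (all non-background, non-cell classes).
ORGANELLE_CLASSES = (2, 3, 4, 5, 6)

DEFAULT_VOXEL_SIZE_NM = (50.0, 10.0, 10.0)
DEFAULT_H5_DATASET = "data"


@dataclass
class ImageVolume:
    """Rank-3 float grayscale volume indexed (z, y, x) with voxel size metadata."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"image volume must be rank 3, got rank {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Rank-3 integer volume over the 7-class schema; holds ground truth or predictions."""

    data: np.ndarray
    classes: tuple[int, ...] = field(default=CLASSES)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be rank 3, got rank {arr.ndim}")
        _validate_labels(arr)
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# Predicted segmentations share the label container.
Segmentation = LabelVolume


def _validate_labels(arr: np.ndarray) -> None:
    bad = (arr < 0) | (arr > max(CLASSES))
    if np.any(bad):
        loc = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"label value {int(arr[loc])} at (z,y,x)={loc} outside class set {{0..6}}"
        )


def _is_hdf5(path: str) -> bool:
    return os.path.splitext(path)[1].lower() in {".h5", ".hdf5", ".hdf"}


def read_volume(
    path: str,
    kind: str = "image",
    dataset: str = DEFAULT_H5_DATASET,
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM,
) -> ImageVolume | LabelVolume:
    """Read a volume from a multi-page TIFF or an HDF5 dataset.

    Parameters
    ----------
    path
        File to read. ``.h5/.hdf5/.hdf`` files are treated as HDF5, anything
        else as TIFF.
    kind
        ``"image"`` for grayscale data, ``"label"`` for segmentations (values
        are validated against the class set).
    dataset
        HDF5 dataset name (ignored for TIFF).
    """
    if kind not in ("image", "label"):
        raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            arr = f[dataset][()]
    else:
        arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:  # single-page stack
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {arr.shape}")
    if kind == "label":
        _validate_labels(arr)
        return LabelVolume(arr)
    return ImageVolume(arr.astype(np.float32), voxel_size_nm=voxel_size_nm)


def write_volume(
    vol: ImageVolume | LabelVolume,
    path: str,
    dataset: str = DEFAULT_H5_DATASET,
) -> None:
    """Write a volume; labels as unsigned 8-bit, images as 32-bit float.

    Round-trips exactly through :func:`read_volume`.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if isinstance(vol, LabelVolume):
        arr = vol.data.astype(np.uint8)
    else:
        arr = vol.data.astype(np.float32)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=arr)
    else:
        # one grayscale page per z-slice (never RGB planes)
        tifffile.imwrite(path, arr, photometric="minisblack")


def normalize_zscore(vol: ImageVolume) -> ImageVolume:
    """Normalize a volume to mean 0 and (population) standard deviation 1."""
    data = vol.data.astype(np.float64)
    if data.size <= 1:
        raise ValueError("cannot z-score a volume with a single voxel")
    std = data.std()
    if std == 0:
        raise ValueError("cannot z-score a zero-variance volume")
    out = (data - data.mean()) / std
    return ImageVolume(out.astype(np.float32), voxel_size_nm=vol.voxel_size_nm)


def bin_lateral(vol: ImageVolume, factor: int) -> ImageVolume:
    """Bin laterally by block-averaging ``factor x factor`` (y, x) blocks.

    The z axis is untouched; lateral voxel size scales by ``factor``.
    """
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    z, y, x = vol.data.shape
    if y % factor or x % factor:
        raise ValueError(
            f"lateral shape ({y},{x}) not divisible by binning factor {factor}"
        )
    out = (
        vol.data.reshape(z, y // factor, factor, x // factor, factor)
        .mean(axis=(2, 4))
        .astype(np.float32)
    )
    vz, vy, vx = vol.voxel_size_nm
    return ImageVolume(out, voxel_size_nm=(vz, vy * factor, vx * factor))
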