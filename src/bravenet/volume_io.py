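"""Core volumetric grid types and NIfTI-1 I/O.

Volumes are stored with array index order (x, y, z), z being the slice
(thin) axis, so a patch size of (64, 64, 8) means 8 slices.  Coordinates
are 0-based and voxel-centred.  No intensity normalization happens at
I/O time: the networks consume raw angiography intensities and adapt via
an initial batch-normalization layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryLabelVolume",
    "ProbabilityVolume",
    "read_volume",
    "read_label_volume",
    "write_volume",
]


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing in millimetres."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D grid, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BinaryLabelVolume(Volume):
    """A 3-D {0,1} grid aligned to a Volume (labels, masks, predictions)."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("label values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)


@dataclass
class ProbabilityVolume(Volume):
    """A 3-D grid of vessel probabilities in [0, 1]."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.data = self.data.astype(np.float32)


def _spacing_affine(voxel_size):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_volume(path) -> Volume:
    """Read a single-channel 3-D NIfTI image as a raw-intensity Volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        data = np.asanyarray(img.dataobj)[..., 0]
    elif len(shape) != 3:
        raise ValueError(
            f"{path}: expected a single-channel 3-D image, got shape {shape}"
        )
    else:
        data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data), spacing)


def read_label_volume(path) -> BinaryLabelVolume:
    """Read a NIfTI file holding a binary {0,1} label volume."""
    v = read_volume(path)
    return BinaryLabelVolume(np.rint(v.data).astype(np.uint8), v.voxel_size)


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1; labels as uint8, probabilities float32."""
    path = Path(path)
    if isinstance(v, BinaryLabelVolume):
        data = v.data.astype(np.uint8)
    elif isinstance(v, ProbabilityVolume):
        data = v.data.astype(np.float32)
    else:
        data = np.asarray(v.data)
        if data.dtype == np.float64:
            data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _spacing_affine(v.voxel_size))
    img.header.set_zooms(v.voxel_size)
    nib.save(img, str(path))
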