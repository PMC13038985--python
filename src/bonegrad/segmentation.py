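"""Binary segmentation of grayscale micro-CT volumes.

Bone is separated from void by a global intensity window (default 80-255 on
8-bit data, both bounds inclusive), followed by a 2D despeckle that deletes
small bright connected components slice by slice.  No smoothing, local
thresholding, or beam-hardening correction is applied here: the grayscale
volume is taken as reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayscaleVolume",
    "BinaryVolume",
    "global_threshold",
    "despeckle_2d",
]


@dataclass
class GrayscaleVolume:
    """A 3D grayscale image.

    ``voxels`` is indexed (z, y, x) with z the longitudinal axis, z = 0 at
    the distal end.  ``voxel_size`` is the isotropic voxel edge in µm.
    """

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryVolume:
    """A boolean bone mask (True = bone) with its provenance.

    ``provenance`` records the threshold bounds and despeckle parameters the
    mask was produced with, so every downstream table can be traced back.
    """

    voxels: np.ndarray
    voxel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def global_threshold(gray: GrayscaleVolume, lower: int = 80, upper: int = 255) -> BinaryVolume:
    """Segment bone as voxels with ``lower <= intensity <= upper`` (inclusive).

    Parameters
    ----------
    gray:
        8-bit grayscale volume.
    lower, upper:
        Intensity window; a voxel at exactly ``lower`` or ``upper`` is bone.
    """
    if not (0 <= lower <= upper <= 255):
        raise ValueError(f"require 0 <= lower <= upper <= 255, got ({lower}, {upper})")
    v = gray.voxels
    mask = (v >= lower) & (v <= upper)
    return BinaryVolume(
        voxels=mask,
        voxel_size=gray.voxel_size,
        provenance={"lower": int(lower), "upper": int(upper)},
    )


# 2D connectivity structures for slice-wise component labelling.
_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def _despeckle_slice(sl: np.ndarray, min_pixels: int, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(sl, structure=structure)
    if n == 0:
        return sl
    counts = np.bincount(labels.ravel())
    small = counts < min_pixels
    small[0] = False  # background label
    if not small.any():
        return sl
    return sl & ~small[labels]


def despeckle_2d(
    binary: BinaryVolume,
    min_pixels: int = 25,
    connectivity: int = 8,
    remove_black: bool = False,
) -> BinaryVolume:
    """Remove small bright components from every transverse (fixed-z) slice.

    A foreground component with strictly fewer than ``min_pixels`` pixels is
    set to background ("smaller than 25 pixels" is read as ``< 25``).  The
    operation is idempotent and only ever removes foreground.

    Parameters
    ----------
    min_pixels:
        Strict size cutoff in pixels.
    connectivity:
        4 or 8; component connectivity within a slice (8 by default, the
        convention of desktop bone-morphometry despeckle filters).
    remove_black:
        Additionally fill interior background components smaller than
        ``min_pixels`` (pore-filling).  Off by default.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4

    out = np.empty_like(binary.voxels)
    for z in range(binary.voxels.shape[0]):
        sl = _despeckle_slice(binary.voxels[z], min_pixels, structure)
        if remove_black:
            inv = _despeckle_slice(~sl, min_pixels, structure)
            sl = ~inv
        out[z] = sl

    prov = dict(binary.provenance)
    prov.update(
        {
            "despeckle_min_pixels": int(min_pixels),
            "despeckle_connectivity": int(connectivity),
            "despeckle_remove_black": bool(remove_black),
        }
    )
    return BinaryVolume(voxels=out, voxel_size=binary.voxel_size, provenance=prov)
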