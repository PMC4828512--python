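"""Peri-hippocampal VOI extraction and the training-derived reduced VOI.

The VOI is a fixed 50x60x60 box cropped from a co-registered whole-brain
volume.  The reduced VOI (rVOI) is the voxelwise OR of the training
hippocampus masks dilated by a small cubic kernel; classification is
restricted to it, since voxels outside the training rVOI cannot belong to
the hippocampus of a co-registered scan (up to the one-kernel margin the
dilation provides for test subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError, InvalidDatasetError

__all__ = ["VOIBox", "RVOI", "DEFAULT_VOI_SHAPE", "extract_voi", "dilate_mask",
           "build_rvoi", "rvoi_stats"]

DEFAULT_VOI_SHAPE = (50, 60, 60)


@dataclass(frozen=True)
class VOIBox:
    """Axis-aligned crop box in the registered full-volume grid (0-based)."""

    origin: Tuple[int, int, int]
    shape: Tuple[int, int, int] = DEFAULT_VOI_SHAPE
    side: str = "left"

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise InvalidArgumentError("VOI shape must be strictly positive")
        if any(o < 0 for o in self.origin):
            raise InvalidArgumentError("VOI origin must be nonnegative")
        if self.side not in ("left", "right"):
            raise InvalidArgumentError("side must be 'left' or 'right'")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class RVOI:
    """Reduced VOI: binary mask plus its deterministic voxel enumeration."""

    mask: np.ndarray
    voxels: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise InvalidDatasetError("rVOI is empty")
        # raster enumeration with x varying fastest (Fortran order)
        zz, yy, xx = np.nonzero(self.mask.transpose(2, 1, 0))
        self.voxels = np.column_stack([xx, yy, zz]).astype(int)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def extract_voi(volume: np.ndarray, box: VOIBox) -> np.ndarray:
    """Crop the VOI subvolume; the default box holds 50*60*60 = 180000 voxels."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise InvalidArgumentError("volume must be 3D")
    hi = np.asarray(box.origin) + np.asarray(box.shape)
    if np.any(hi > np.asarray(volume.shape)):
        raise InvalidArgumentError(
            f"VOI box origin={box.origin} shape={box.shape} exceeds volume {volume.shape}"
        )
    x0, y0, z0 = box.origin
    sx, sy, sz = box.shape
    return volume[x0:x0 + sx, y0:y0 + sy, z0:z0 + sz].copy()


def dilate_mask(mask: np.ndarray, kernel: Tuple[int, int, int]) -> np.ndarray:
    """Morphological dilation by a cubic kernel anchored at its low corner.

    The structuring element covers offsets {0..k_a - 1} along each axis, so a
    (1,1,1) kernel is the identity and a (2,2,2) kernel maps a single voxel v
    to the 8-voxel cube {v, v+1}^3.
    """
    mask = np.asarray(mask).astype(bool)
    kernel = tuple(int(k) for k in kernel)
    if any(k < 1 for k in kernel):
        raise InvalidArgumentError("kernel entries must be >= 1")
    out = np.zeros_like(mask)
    for dx in range(kernel[0]):
        for dy in range(kernel[1]):
            for dz in range(kernel[2]):
                shifted = mask
                for axis, d in enumerate((dx, dy, dz)):
                    if d:
                        pad = [(0, 0)] * 3
                        pad[axis] = (d, 0)
                        shifted = np.pad(shifted, pad)[
                            tuple(
                                slice(0, mask.shape[a]) if a == axis else slice(None)
                                for a in range(3)
                            )
                        ]
                out |= shifted
    return out


def build_rvoi(training_masks: Sequence[np.ndarray],
               dilation_kernel: Tuple[int, int, int] = (2, 2, 2)) -> RVOI:
    """Voxelwise OR of the training masks, dilated by the cubic kernel."""
    masks = [np.asarray(m).astype(bool) for m in training_masks]
    if not masks:
        raise InvalidArgumentError("at least one training mask is required")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise InvalidArgumentError(
                f"mask grid mismatch: {m.shape} vs {shape}"
            )
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m
    if not union.any():
        raise InvalidDatasetError("union of training masks is empty")
    return RVOI(dilate_mask(union, dilation_kernel))


def rvoi_stats(rvoi: RVOI, training_masks: Sequence[np.ndarray]
               ) -> Tuple[int, float]:
    """(rVOI voxel count, mean hippocampal percentage of the rVOI).

    The percentage is the mean over training masks of the mask voxel count,
    divided by the rVOI size, expressed in percent.
    """
    counts = [float(np.asarray(m).astype(bool).sum()) for m in training_masks]
    size = rvoi.size
    return size, 100.0 * float(np.mean(counts)) / size
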