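"""NIfTI-1 reading/writing for volumes and binary masks (via nibabel)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .errors import FormatError, InvalidArgumentError

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_MASK_TOL = 1e-6


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data as float64, 4x4 affine).

    The affine is carried through for round-tripping but never interpreted:
    all volumes are assumed co-registered on a shared grid.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine)


def write_volume(volume: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise InvalidArgumentError("volume must be 3D")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(volume, affine), str(path))


def read_mask(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a binary mask; values must be 0/1 within a 1e-6 rounding tolerance."""
    data, affine = read_volume(path)
    rounded = np.rint(data)
    if np.any(np.abs(data - rounded) > _MASK_TOL) or not np.all(
        np.isin(rounded, (0.0, 1.0))
    ):
        bad = np.unique(data[~np.isin(rounded, (0.0, 1.0)) |
                             (np.abs(data - rounded) > _MASK_TOL)])
        raise InvalidArgumentError(
            f"{path}: mask contains non-binary values, e.g. {bad[:5].tolist()}"
        )
    return rounded.astype(bool), affine


def write_mask(mask: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    mask = np.asarray(mask)
    write_volume(mask.astype(np.float64), path, affine)
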