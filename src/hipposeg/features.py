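"""Per-voxel feature schema and extraction.

Every voxel is described by a 315-dimensional vector, concatenated in the
fixed order

    [ 248 Haar-like | 48 Haralick | 16 gradient | 3 position ]

The Haar bank and Haralick statistics live in :mod:`hipposeg.haar` and
:mod:`hipposeg.haralick`; this module adds the symmetric intensity gradients
(4 directions x 4 distances) and the VOI-relative voxel position, assembles
the named schema, and provides both the vectorised batch extractor used by
the pipeline and a naive per-voxel reference path used for verification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import haar, haralick
from .errors import InvalidArgumentError

__all__ = [
    "GRADIENT_DIRECTIONS",
    "GRADIENT_DISTANCES",
    "FeatureDescriptor",
    "FeatureSchema",
    "default_schema",
    "gradient_features",
    "gradient_features_batch",
    "position_features",
    "extract_feature_matrix",
    "reference_feature_vector",
    "feature_matrix_to_csv",
]

GRADIENT_DIRECTIONS: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
)
GRADIENT_DISTANCES: Tuple[int, ...] = (1, 2, 3, 4)
N_GRADIENT = len(GRADIENT_DIRECTIONS) * len(GRADIENT_DISTANCES)
N_POSITION = 3
N_TOTAL = haar.N_HAAR + haralick.N_HARALICK + N_GRADIENT + N_POSITION

GROUP_COUNTS = {
    "haar": haar.N_HAAR,
    "haralick": haralick.N_HARALICK,
    "gradient": N_GRADIENT,
    "position": N_POSITION,
}


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    group: str
    params: dict = field(default_factory=dict)


@dataclass
class FeatureSchema:
    """Ordered, named description of the per-voxel feature vector."""

    descriptors: List[FeatureDescriptor]

    def __post_init__(self):
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("duplicate feature names in schema")
        counts = {g: 0 for g in GROUP_COUNTS}
        for d in self.descriptors:
            if d.group not in counts:
                raise InvalidArgumentError(f"unknown feature group {d.group!r}")
            counts[d.group] += 1
        if counts != GROUP_COUNTS:
            raise InvalidArgumentError(
                f"schema group counts {counts} != required {GROUP_COUNTS}"
            )

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> List[str]:
        return [d.name for d in self.descriptors]

    def group_slice(self, group: str) -> slice:
        idx = [i for i, d in enumerate(self.descriptors) if d.group == group]
        return slice(idx[0], idx[-1] + 1)

    def to_json(self) -> str:
        return json.dumps(
            [
                {"name": d.name, "group": d.group, "params": d.params}
                for d in self.descriptors
            ],
            sort_keys=True,
        )

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def gradient_feature_names() -> List[str]:
    return [
        f"grad_{''.join(map(str, d))}_d{k}"
        for d in GRADIENT_DIRECTIONS
        for k in GRADIENT_DISTANCES
    ]


def default_schema(levels: int = haralick.DEFAULT_LEVELS) -> FeatureSchema:
    desc: List[FeatureDescriptor] = []
    for s in haar.SCALES:
        for name, _ in haar.haar_catalog():
            desc.append(
                FeatureDescriptor(f"haar_s{s}_{name}", "haar",
                                  {"scale": s, "template": name})
            )
    for n in haralick.SIZES:
        for ax in "xyz":
            for st in haralick.STAT_NAMES:
                desc.append(
                    FeatureDescriptor(
                        f"haralick_n{n}_proj{ax}_{st}", "haralick",
                        {"size": n, "projection": ax, "statistic": st,
                         "levels": levels, "offset": [1, 0]},
                    )
                )
    for d in GRADIENT_DIRECTIONS:
        for k in GRADIENT_DISTANCES:
            desc.append(
                FeatureDescriptor(
                    f"grad_{''.join(map(str, d))}_d{k}", "gradient",
                    {"direction": list(d), "distance": k},
                )
            )
    for ax in "xyz":
        desc.append(FeatureDescriptor(f"pos_{ax}", "position", {"axis": ax}))
    return FeatureSchema(desc)


def _clip_index(volume_shape, coords):
    return tuple(
        np.clip(c, 0, n - 1) for c, n in zip(coords, volume_shape)
    )


def gradient_features(volume: np.ndarray, voxel) -> np.ndarray:
    """Symmetric finite differences I(v + d*dir) - I(v - d*dir), 16 values.

    Out-of-volume lookups are clipped to the border (edge replication).
    """
    volume = np.asarray(volume, dtype=float)
    v = np.asarray(voxel, dtype=int)
    if np.any(v < 0) or np.any(v >= np.array(volume.shape)):
        raise InvalidArgumentError(f"voxel {voxel} outside volume of shape {volume.shape}")
    out = np.empty(N_GRADIENT)
    i = 0
    for d in GRADIENT_DIRECTIONS:
        d = np.asarray(d)
        for k in GRADIENT_DISTANCES:
            fwd = _clip_index(volume.shape, v + k * d)
            bwd = _clip_index(volume.shape, v - k * d)
            out[i] = volume[fwd] - volume[bwd]
            i += 1
    return out


def gradient_features_batch(volume: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume, dtype=float)
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size and (np.any(voxels < 0) or np.any(voxels >= np.array(volume.shape))):
        raise InvalidArgumentError("voxels outside volume")
    out = np.empty((voxels.shape[0], N_GRADIENT))
    i = 0
    for d in GRADIENT_DIRECTIONS:
        d = np.asarray(d)
        for k in GRADIENT_DISTANCES:
            fwd = _clip_index(volume.shape, (voxels + k * d).T)
            bwd = _clip_index(volume.shape, (voxels - k * d).T)
            out[:, i] = volume[fwd] - volume[bwd]
            i += 1
    return out


def position_features(voxel, voi_shape) -> np.ndarray:
    """The voxel's 0-based (x, y, z) indices within the VOI grid."""
    v = np.asarray(voxel, dtype=int)
    shape = np.asarray(voi_shape, dtype=int)
    if np.any(v < 0) or np.any(v >= shape):
        raise InvalidArgumentError(f"voxel {voxel} outside VOI of shape {tuple(voi_shape)}")
    return v.astype(float)


def reference_feature_vector(volume: np.ndarray, voxel,
                             levels: int = haralick.DEFAULT_LEVELS) -> np.ndarray:
    """Naive per-voxel feature vector (no integral-image / vectorization)."""
    return np.concatenate(
        [
            haar.haar_features(volume, voxel),
            haralick.haralick_features(volume, voxel, levels=levels),
            gradient_features(volume, voxel),
            position_features(voxel, np.asarray(volume).shape),
        ]
    )


def extract_feature_matrix(
    volume: np.ndarray,
    voxels: Sequence,
    schema: Optional[FeatureSchema] = None,
    levels: int = haralick.DEFAULT_LEVELS,
) -> np.ndarray:
    """Feature matrix (len(voxels) x 315) in schema order.

    Rows concatenate [haar | haralick | gradient | position].  Raises if any
    voxel lies outside the volume, naming the offenders.
    """
    volume = np.asarray(volume, dtype=float)
    voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
    if voxels.shape[0] == 0:
        return np.empty((0, N_TOTAL))
    oob = np.any((voxels < 0) | (voxels >= np.array(volume.shape)), axis=1)
    if np.any(oob):
        raise InvalidArgumentError(
            f"voxels outside volume {volume.shape}: {voxels[oob][:10].tolist()}"
        )
    if schema is not None and len(schema) != N_TOTAL:
        raise InvalidArgumentError("schema size mismatch")
    return np.concatenate(
        [
            haar.haar_features_batch(volume, voxels),
            haralick.haralick_features_batch(volume, voxels, levels=levels),
            gradient_features_batch(volume, voxels),
            voxels.astype(float),
        ],
        axis=1,
    )


def feature_matrix_to_csv(matrix: np.ndarray, schema: FeatureSchema, path) -> None:
    """Write a headered CSV, one row per voxel, columns named from the schema."""
    pd.DataFrame(np.asarray(matrix), columns=schema.names).to_csv(path, index=False)
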