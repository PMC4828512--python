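"""Haralick texture statistics on projection subimages: 48 features per voxel.

For each odd neighbourhood size n in {3, 5, 7, 9} the n^3 cube around the
voxel (edge-replicated at borders) is mean-projected along each of the three
axes, yielding three n x n subimages.  Each subimage is min-max quantized to
G gray levels, a symmetrized gray-level co-occurrence matrix (GLCM) is
accumulated at offset (1, 0), and four statistics are read off: energy,
contrast, correlation and inverse difference moment.
4 sizes x 3 projections x 4 statistics = 48 features.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "SIZES",
    "STAT_NAMES",
    "DEFAULT_LEVELS",
    "glcm_matrix",
    "haralick_stats",
    "haralick_feature_names",
    "haralick_features",
    "haralick_features_batch",
    "N_HARALICK",
]

SIZES = (3, 5, 7, 9)
STAT_NAMES = ("energy", "contrast", "correlation", "idm")
DEFAULT_LEVELS = 8
N_HARALICK = len(SIZES) * 3 * len(STAT_NAMES)

_VAR_EPS = 1e-12


def quantize(subimage: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization of a subimage to integer levels 0..G-1.

    A constant subimage maps entirely to level 0.
    """
    subimage = np.asarray(subimage, dtype=float)
    lo, hi = subimage.min(), subimage.max()
    if hi <= lo:
        return np.zeros(subimage.shape, dtype=np.int64)
    q = np.floor((subimage - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(subimage: np.ndarray, levels: int = DEFAULT_LEVELS,
                offset: Tuple[int, int] = (1, 0)) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix of a 2D grid.

    Intensities are min-max quantized to ``levels`` within the subimage;
    co-occurring level pairs are counted at ``offset`` and its negation and
    the matrix is normalized to sum to 1.
    """
    subimage = np.asarray(subimage, dtype=float)
    if subimage.ndim != 2 or min(subimage.shape) < 2:
        raise InvalidArgumentError("subimage must be at least 2x2")
    if levels < 2:
        raise InvalidArgumentError("levels must be >= 2")
    dr, dc = int(offset[0]), int(offset[1])
    if (dr, dc) == (0, 0):
        raise InvalidArgumentError("offset must be nonzero")
    nr, nc = subimage.shape
    if nr <= abs(dr) or nc <= abs(dc):
        raise InvalidArgumentError(
            f"subimage shape {subimage.shape} degenerate for offset {offset}"
        )
    q = quantize(subimage, levels)
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    return counts / counts.sum()


def haralick_stats(glcm: np.ndarray) -> Tuple[float, float, float, float]:
    """(energy, contrast, correlation, inverse difference moment) of a GLCM.

    correlation is defined as 0 when either marginal is degenerate
    (zero variance).
    """
    P = np.asarray(glcm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidArgumentError("GLCM must be square")
    if abs(P.sum() - 1.0) > 1e-6 or np.any(P < 0):
        raise InvalidArgumentError("GLCM must be nonnegative and normalized to sum 1")
    G = P.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    energy = float(np.sum(P * P))
    contrast = float(np.sum((i - j) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(G) * pi))
    mu_j = float(np.sum(np.arange(G) * pj))
    var_i = float(np.sum((np.arange(G) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(G) - mu_j) ** 2 * pj))
    denom = np.sqrt(var_i * var_j)
    if denom <= _VAR_EPS:
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / denom)
    return energy, contrast, correlation, idm


def haralick_feature_names() -> List[str]:
    return [
        f"haralick_n{n}_proj{ax}_{st}"
        for n in SIZES
        for ax in "xyz"
        for st in STAT_NAMES
    ]


def _neighbourhood(volume: np.ndarray, voxel, r: int) -> np.ndarray:
    x, y, z = voxel
    nx, ny, nz = volume.shape
    xs = np.clip(np.arange(x - r, x + r + 1), 0, nx - 1)
    ys = np.clip(np.arange(y - r, y + r + 1), 0, ny - 1)
    zs = np.clip(np.arange(z - r, z + r + 1), 0, nz - 1)
    return volume[np.ix_(xs, ys, zs)]


def haralick_features(volume: np.ndarray, voxel,
                      levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Reference per-voxel extractor: explicit projection -> GLCM -> stats."""
    volume = np.asarray(volume, dtype=float)
    v = tuple(int(c) for c in voxel)
    if any(c < 0 or c >= n for c, n in zip(v, volume.shape)):
        raise InvalidArgumentError(f"voxel {voxel} outside volume of shape {volume.shape}")
    out = np.empty(N_HARALICK)
    col = 0
    for n in SIZES:
        cube = _neighbourhood(volume, v, n // 2)
        for axis in range(3):
            sub = cube.mean(axis=axis)
            P = glcm_matrix(sub, levels=levels, offset=(1, 0))
            out[col:col + 4] = haralick_stats(P)
            col += 4
    return out


def _axis_mean(volume: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Running mean of length n along one axis with edge replication."""
    r = n // 2
    pad = [(0, 0)] * 3
    pad[axis] = (r, r)
    vp = np.pad(volume, pad, mode="edge")
    acc = np.zeros(volume.shape, dtype=float)
    for d in range(n):
        sl = [slice(None)] * 3
        sl[axis] = slice(d, d + volume.shape[axis])
        acc += vp[tuple(sl)]
    return acc / n


def haralick_features_batch(volume: np.ndarray, voxels: np.ndarray,
                            levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Vectorised extraction at many voxels: (n_voxels, 48).

    The per-voxel n x n projection subimages are gathered from a single
    full-volume running mean per (size, axis); GLCM statistics are computed
    from per-voxel pair-code histograms via one bincount per combination.
    """
    volume = np.asarray(volume, dtype=float)
    voxels = np.asarray(voxels, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise InvalidArgumentError("voxels must be an (n, 3) index array")
    if voxels.size and (np.any(voxels < 0) or np.any(voxels >= np.array(volume.shape))):
        raise InvalidArgumentError("voxels outside volume")
    N = voxels.shape[0]
    out = np.empty((N, N_HARALICK))
    G = levels
    lev = np.arange(G, dtype=float)
    col = 0
    for n in SIZES:
        r = n // 2
        offs = np.arange(-r, r + 1)
        for axis in range(3):
            M = _axis_mean(volume, n, axis)
            inplane = [a for a in range(3) if a != axis]
            u_ax, v_ax = inplane
            # gather the n x n subimage values per voxel (edge replication
            # via coordinate clipping)
            cu = np.clip(voxels[:, u_ax][:, None] + offs[None, :], 0,
                         volume.shape[u_ax] - 1)          # (N, n)
            cv = np.clip(voxels[:, v_ax][:, None] + offs[None, :], 0,
                         volume.shape[v_ax] - 1)          # (N, n)
            coords = [None, None, None]
            coords[axis] = voxels[:, axis][:, None, None]
            coords[u_ax] = cu[:, :, None]
            coords[v_ax] = cv[:, None, :]
            vals = M[tuple(coords)]                        # (N, n, n)
            lo = vals.min(axis=(1, 2))
            hi = vals.max(axis=(1, 2))
            rng = hi - lo
            safe = rng > 0
            q = np.zeros_like(vals, dtype=np.int64)
            if np.any(safe):
                scaled = np.floor(
                    (vals[safe] - lo[safe, None, None]) / rng[safe, None, None] * G
                )
                q[safe] = np.clip(scaled, 0, G - 1).astype(np.int64)
            # symmetric pairs at offset (1, 0) along the first in-plane axis
            a = q[:, :-1, :].reshape(N, -1)
            b = q[:, 1:, :].reshape(N, -1)
            row = (np.arange(N, dtype=np.int64)[:, None] * (G * G))
            codes = np.concatenate([row + a * G + b, row + b * G + a], axis=1)
            counts = np.bincount(codes.ravel(), minlength=N * G * G).astype(float)
            P = counts.reshape(N, G, G)
            P /= P.sum(axis=(1, 2), keepdims=True)
            ii = lev[None, :, None]
            jj = lev[None, None, :]
            energy = np.sum(P * P, axis=(1, 2))
            contrast = np.sum((ii - jj) ** 2 * P, axis=(1, 2))
            idm = np.sum(P / (1.0 + (ii - jj) ** 2), axis=(1, 2))
            pi = P.sum(axis=2)
            mu = np.sum(lev[None, :] * pi, axis=1)
            var = np.sum((lev[None, :] - mu[:, None]) ** 2 * pi, axis=1)
            num = np.sum((ii - mu[:, None, None]) * (jj - mu[:, None, None]) * P,
                         axis=(1, 2))
            correlation = np.where(var > _VAR_EPS, num / np.maximum(var, _VAR_EPS), 0.0)
            out[:, col + 0] = energy
            out[:, col + 1] = contrast
            out[:, col + 2] = correlation
            out[:, col + 3] = idm
            col += 4
    return out
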