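"""3D Haar-like filter bank: 62 block templates at 4 cubic scales = 248 features.

Each feature is a signed combination of mean intensities over axis-aligned
sub-blocks of an s^3 window (s in {3, 5, 7, 9}) centred on the query voxel.
Difference templates have weights summing to 0 (zero response on constant
images); pure-average templates have weights summing to 1.  The catalogue is
enumerated below as data; its size (62 per scale) is locked by tests.

Out-of-volume voxels are handled by edge replication everywhere.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "SCALES",
    "haar_catalog",
    "block_bounds",
    "haar_feature_names",
    "haar_features",
    "haar_features_batch",
    "N_HAAR",
]

SCALES = (3, 5, 7, 9)
MAX_RADIUS = max(SCALES) // 2

Block = Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]

_AXES = "xyz"
_SIGNS = {"n": -1, "p": +1}


def block_bounds(r: int) -> Dict[str, Block]:
    """Named axis-aligned blocks of the (2r+1)^3 window, inclusive bounds
    relative to the centre voxel."""
    full = (-r, r)
    neg, pos = (-r, -1), (1, r)
    mid = (0, 0)
    h = max(1, (r + 1) // 2)  # inner cube at roughly half scale
    blocks: Dict[str, Block] = {"full": (full, full, full)}
    for a in range(3):
        for sname, side in (("neg", neg), ("pos", pos)):
            b = [full, full, full]
            b[a] = side
            blocks[f"half_{_AXES[a]}_{sname}"] = tuple(b)
        b = [full, full, full]
        b[a] = mid
        blocks[f"plane_{_AXES[a]}"] = tuple(b)
        b = [mid, mid, mid]
        b[a] = full
        blocks[f"row_{_AXES[a]}"] = tuple(b)
    for a, b_ in ((0, 1), (0, 2), (1, 2)):
        pair = _AXES[a] + _AXES[b_]
        for sa in "np":
            for sb in "np":
                bb = [full, full, full]
                bb[a] = neg if sa == "n" else pos
                bb[b_] = neg if sb == "n" else pos
                blocks[f"quad_{pair}_{sa}{sb}"] = tuple(bb)
    for sx in "np":
        for sy in "np":
            for sz in "np":
                bb = (
                    neg if sx == "n" else pos,
                    neg if sy == "n" else pos,
                    neg if sz == "n" else pos,
                )
                blocks[f"oct_{sx}{sy}{sz}"] = bb
    blocks["center"] = (mid, mid, mid)
    blocks["inner"] = ((-h, h), (-h, h), (-h, h))
    return blocks


def _build_catalog() -> List[Tuple[str, List[Tuple[str, float]]]]:
    cat: List[Tuple[str, List[Tuple[str, float]]]] = []
    # 1 full-window average
    cat.append(("full_mean", [("full", 1.0)]))
    # 6 half-slab means + 3 half differences + 3 half-vs-full contrasts
    for a in _AXES:
        cat.append((f"half_{a}_neg_mean", [(f"half_{a}_neg", 1.0)]))
        cat.append((f"half_{a}_pos_mean", [(f"half_{a}_pos", 1.0)]))
    for a in _AXES:
        cat.append((f"half_diff_{a}", [(f"half_{a}_pos", 1.0), (f"half_{a}_neg", -1.0)]))
    for a in _AXES:
        cat.append((f"half_{a}_pos_vs_full", [(f"half_{a}_pos", 1.0), ("full", -1.0)]))
    # 3 centre-plane means + 3 plane-vs-full contrasts
    for a in _AXES:
        cat.append((f"plane_{a}_mean", [(f"plane_{a}", 1.0)]))
    for a in _AXES:
        cat.append((f"plane_{a}_vs_full", [(f"plane_{a}", 1.0), ("full", -1.0)]))
    # 12 quadrant means + 3 diagonal contrasts + 6 opposite-quadrant diffs
    pairs = ("xy", "xz", "yz")
    for p in pairs:
        for q in ("nn", "np", "pn", "pp"):
            cat.append((f"quad_{p}_{q}_mean", [(f"quad_{p}_{q}", 1.0)]))
    for p in pairs:
        cat.append(
            (
                f"quad_diag_{p}",
                [
                    (f"quad_{p}_pp", 0.5),
                    (f"quad_{p}_nn", 0.5),
                    (f"quad_{p}_pn", -0.5),
                    (f"quad_{p}_np", -0.5),
                ],
            )
        )
    for p in pairs:
        cat.append((f"quad_diff_{p}_main", [(f"quad_{p}_pp", 1.0), (f"quad_{p}_nn", -1.0)]))
        cat.append((f"quad_diff_{p}_anti", [(f"quad_{p}_pn", 1.0), (f"quad_{p}_np", -1.0)]))
    # 8 octant means + 1 checkerboard + 4 opposite-octant diffs
    octs = [s1 + s2 + s3 for s1 in "np" for s2 in "np" for s3 in "np"]
    for o in octs:
        cat.append((f"oct_{o}_mean", [(f"oct_{o}", 1.0)]))
    cat.append(
        (
            "oct_checker",
            [
                (f"oct_{o}", 0.25 if o.count("p") % 2 == 0 else -0.25)
                for o in octs
            ],
        )
    )
    for o in ("ppp", "ppn", "pnp", "pnn"):
        mirror = "".join("n" if c == "p" else "p" for c in o)
        cat.append((f"oct_diff_{o}", [(f"oct_{o}", 1.0), (f"oct_{mirror}", -1.0)]))
    # 3 centre-row means + 3 row-vs-full contrasts
    for a in _AXES:
        cat.append((f"row_{a}_mean", [(f"row_{a}", 1.0)]))
    for a in _AXES:
        cat.append((f"row_{a}_vs_full", [(f"row_{a}", 1.0), ("full", -1.0)]))
    # centre voxel, centre-vs-full, inner-cube mean
    cat.append(("center_mean", [("center", 1.0)]))
    cat.append(("center_vs_full", [("center", 1.0), ("full", -1.0)]))
    cat.append(("inner_mean", [("inner", 1.0)]))
    return cat


_CATALOG = _build_catalog()
assert len(_CATALOG) == 62, f"Haar catalogue has {len(_CATALOG)} templates, expected 62"
N_HAAR = len(SCALES) * len(_CATALOG)


def haar_catalog() -> List[Tuple[str, List[Tuple[str, float]]]]:
    """The 62-template catalogue: (name, [(block name, weight), ...])."""
    return list(_CATALOG)


def haar_feature_names() -> List[str]:
    return [f"haar_s{s}_{name}" for s in SCALES for name, _ in _CATALOG]


def _check_voxel(volume: np.ndarray, voxel) -> Tuple[int, int, int]:
    v = tuple(int(c) for c in voxel)
    if len(v) != 3 or any(c < 0 or c >= n for c, n in zip(v, volume.shape)):
        raise InvalidArgumentError(f"voxel {voxel} outside volume of shape {volume.shape}")
    return v


def haar_features(volume: np.ndarray, voxel) -> np.ndarray:
    """Reference per-voxel extractor: direct block means, no acceleration."""
    volume = np.asarray(volume, dtype=float)
    x, y, z = _check_voxel(volume, voxel)
    nx, ny, nz = volume.shape
    out = np.empty(N_HAAR)
    col = 0
    for s in SCALES:
        r = s // 2
        # edge-replicated neighbourhood via clipped coordinates
        xs = np.clip(np.arange(x - r, x + r + 1), 0, nx - 1)
        ys = np.clip(np.arange(y - r, y + r + 1), 0, ny - 1)
        zs = np.clip(np.arange(z - r, z + r + 1), 0, nz - 1)
        cube = volume[np.ix_(xs, ys, zs)]
        blocks = block_bounds(r)
        for _, terms in _CATALOG:
            resp = 0.0
            for bname, w in terms:
                (x0, x1), (y0, y1), (z0, z1) = blocks[bname]
                sub = cube[x0 + r:x1 + r + 1, y0 + r:y1 + r + 1, z0 + r:z1 + r + 1]
                resp += w * sub.mean()
            out[col] = resp
            col += 1
    return out


def _integral_image(vol: np.ndarray) -> np.ndarray:
    I = np.zeros(tuple(n + 1 for n in vol.shape), dtype=float)
    I[1:, 1:, 1:] = vol.cumsum(0).cumsum(1).cumsum(2)
    return I


def _block_mean(I, px, py, pz, bounds: Block) -> np.ndarray:
    (x0, x1), (y0, y1), (z0, z1) = bounds
    a0, a1 = px + x0, px + x1 + 1
    b0, b1 = py + y0, py + y1 + 1
    c0, c1 = pz + z0, pz + z1 + 1
    s = (
        I[a1, b1, c1] - I[a0, b1, c1] - I[a1, b0, c1] - I[a1, b1, c0]
        + I[a0, b0, c1] + I[a0, b1, c0] + I[a1, b0, c0] - I[a0, b0, c0]
    )
    count = (x1 - x0 + 1) * (y1 - y0 + 1) * (z1 - z0 + 1)
    return s / count


def haar_features_batch(volume: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Integral-image accelerated extraction at many voxels: (n, 248)."""
    volume = np.asarray(volume, dtype=float)
    voxels = np.asarray(voxels, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3:
        raise InvalidArgumentError("voxels must be an (n, 3) index array")
    if voxels.size and (
        np.any(voxels < 0) or np.any(voxels >= np.array(volume.shape))
    ):
        bad = voxels[
            np.any((voxels < 0) | (voxels >= np.array(volume.shape)), axis=1)
        ]
        raise InvalidArgumentError(f"voxels outside volume: {bad[:5].tolist()}...")
    padded = np.pad(volume, MAX_RADIUS, mode="edge")
    I = _integral_image(padded)
    px = voxels[:, 0] + MAX_RADIUS
    py = voxels[:, 1] + MAX_RADIUS
    pz = voxels[:, 2] + MAX_RADIUS
    out = np.empty((voxels.shape[0], N_HAAR))
    col = 0
    for s in SCALES:
        r = s // 2
        blocks = block_bounds(r)
        cache: Dict[str, np.ndarray] = {}
        for _, terms in _CATALOG:
            resp = np.zeros(voxels.shape[0])
            for bname, w in terms:
                if bname not in cache:
                    cache[bname] = _block_mean(I, px, py, pz, blocks[bname])
                resp += w * cache[bname]
            out[:, col] = resp
            col += 1
    return out
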