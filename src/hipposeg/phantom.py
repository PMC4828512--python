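"""Synthetic peri-hippocampal phantoms with ground-truth masks.

Each phantom emulates, on the standard 50x60x60 VOI grid, the statistical
challenges of real peri-hippocampal MR data rather than its anatomy: a
compact, irregular minority-class foreground structure (a randomly deformed,
translated and volume-scaled ellipsoid standing in for the hippocampus),
textured foreground/background intensities, a smooth multiplicative
intensity-inhomogeneity (bias) field, and additive Gaussian noise.
Across-subject variability comes from per-subject random deformation,
translation and volume scaling, so cohorts exhibit realistic volume spread
for volume-agreement analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError
from .voi import DEFAULT_VOI_SHAPE

__all__ = ["PhantomSpec", "CohortDataset", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; the defaults define the study conditions.

    Intensities are arbitrary MR-like units: background mean 100 with a +40
    foreground offset, smoothed-noise texture of amplitude 6, an up-to-±8%
    smooth bias field and voxelwise Gaussian noise of sd 5.  The base
    ellipsoid occupies ~5.8% of the grid, keeping the hippocampus-like
    structure a clear minority class across the volume-scaling and
    deformation range.
    """

    grid_shape: Tuple[int, int, int] = DEFAULT_VOI_SHAPE
    semi_axes: Tuple[float, float, float] = (11.0, 15.0, 15.0)
    center: Optional[Tuple[float, float, float]] = None
    deform_amplitude: float = 0.18
    deform_smoothness: float = 6.0
    max_translation: int = 4
    volume_scale_range: Tuple[float, float] = (0.85, 1.15)
    background_mean: float = 100.0
    foreground_offset: float = 40.0
    texture_amplitude: float = 6.0
    texture_smoothness: float = 2.0
    bias_amplitude: float = 0.08
    noise_sd: float = 5.0
    foreground_fraction_band: Tuple[float, float] = (0.03, 0.12)

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise InvalidArgumentError("semi-axes must be positive")
        if any(2 * a >= n for a, n in zip(self.semi_axes, self.grid_shape)):
            raise InvalidArgumentError("ellipsoid does not fit in the grid")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise sd must be >= 0")
        lo, hi = self.volume_scale_range
        if not (0.5 < lo <= hi < 1.5):
            raise InvalidArgumentError("volume scale range must lie within (0.5, 1.5)")


@dataclass
class CohortDataset:
    """A list of (subject id, volume, mask) triples sharing the VOI grid."""

    subjects: List[Tuple[str, np.ndarray, np.ndarray]]
    side: str = "left"

    def __len__(self) -> int:
        return len(self.subjects)

    def volumes(self) -> List[np.ndarray]:
        return [v for _, v, _ in self.subjects]

    def masks(self) -> List[np.ndarray]:
        return [m for _, _, m in self.subjects]


def _smooth_field(shape, rng, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _bias_field(shape, rng, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (low-order polynomial)."""
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    terms = list(coords) + [c * c for c in coords] + [
        coords[0] * coords[1], coords[0] * coords[2], coords[1] * coords[2]
    ]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    poly = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + amplitude * poly


def _draw_mask(spec: PhantomSpec, rng) -> np.ndarray:
    shape = spec.grid_shape
    center = np.array(
        spec.center if spec.center is not None else [n / 2.0 for n in shape]
    )
    center = center + rng.integers(-spec.max_translation,
                                   spec.max_translation + 1, size=3)
    scale = rng.uniform(*spec.volume_scale_range) ** (1.0 / 3.0)
    axes = np.array(spec.semi_axes) * scale
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    bump = _smooth_field(shape, rng, spec.deform_smoothness)
    radius = 1.0 + spec.deform_amplitude * bump
    return rho2 <= radius ** 2


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator
                     ) -> Tuple[np.ndarray, np.ndarray, int]:
    """One (volume, mask, true foreground voxel count) triple.

    The mask is regenerated (up to 10 tries) if it touches the grid boundary
    or comes out disconnected.
    """
    mask = None
    for _ in range(10):
        cand = _draw_mask(spec, rng)
        n_comp = ndimage.label(cand)[1]
        if cand.any() and n_comp == 1 and not _touches_boundary(cand):
            mask = cand
            break
    if mask is None:
        raise InvalidArgumentError(
            "could not draw an interior connected mask in 10 tries; "
            "check semi-axes / translation settings"
        )
    shape = spec.grid_shape
    vol = np.full(shape, spec.background_mean, dtype=float)
    vol[mask] += spec.foreground_offset
    if spec.texture_amplitude > 0:
        vol += spec.texture_amplitude * _smooth_field(
            shape, rng, spec.texture_smoothness
        )
    if spec.bias_amplitude > 0:
        vol *= _bias_field(shape, rng, spec.bias_amplitude)
    if spec.noise_sd > 0:
        vol += spec.noise_sd * rng.standard_normal(shape)
    return vol, mask, int(mask.sum())


def generate_cohort(n: int, spec: PhantomSpec = PhantomSpec(),
                    seed: int = 0, side: str = "left"
                    ) -> Tuple[CohortDataset, pd.DataFrame]:
    """n independent phantoms plus a per-subject true-volume table."""
    if n < 1:
        raise InvalidArgumentError("cohort size must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    subjects = []
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        vol, mask, true_vol = generate_phantom(spec, rng)
        sid = f"sub-{i:03d}"
        subjects.append((sid, vol, mask))
        records.append({"subject": sid, "true_volume_voxels": true_vol})
    table = pd.DataFrame.from_records(records)
    return CohortDataset(subjects, side=side), table
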