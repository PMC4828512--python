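"""Training-set assembly, segmenter training, segmentation and cross-validation.

One cross-validation round draws ``m`` training subjects at random, builds
the rVOI from their manual masks, extracts the 315-feature vector at every
rVOI voxel of every training image (labels +1 at mask voxels, -1 elsewhere),
trains the boosted classifier, and evaluates the four overlap metrics on the
held-out subjects.  Repeated random train/test partitions give the
mean +/- sd tables; rVOI sizes are averaged across rounds alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import rusboost
from .errors import InvalidArgumentError
from .features import FeatureSchema, default_schema, extract_feature_matrix
from .metrics import overlap_metrics
from .phantom import CohortDataset
from .rusboost import BoostModel, train_boost
from .voi import RVOI, build_rvoi, rvoi_stats

__all__ = [
    "SegmenterModel",
    "assemble_training_set",
    "train_segmenter",
    "segment_image",
    "cross_validate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dice", "precision", "recall", "relative_overlap")


@dataclass
class SegmenterModel:
    """A trained segmenter: rVOI restriction + feature schema + boosted votes."""

    rvoi: RVOI
    schema: FeatureSchema
    boost: BoostModel
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "format": "hipposeg-segmenter",
            "version": 1,
            "rvoi_shape": list(self.rvoi.mask.shape),
            "rvoi_voxels": self.rvoi.voxels.tolist(),
            "schema": json.loads(self.schema.to_json()),
            "boost": json.loads(self.boost.to_json()),
            "provenance": self.provenance,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @staticmethod
    def from_json(text: str) -> "SegmenterModel":
        doc = json.loads(text)
        if doc.get("format") != "hipposeg-segmenter":
            raise InvalidArgumentError("not a hipposeg segmenter document")
        mask = np.zeros(tuple(doc["rvoi_shape"]), dtype=bool)
        vox = np.asarray(doc["rvoi_voxels"], dtype=int)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        from .features import FeatureDescriptor  # local to avoid cycle at import

        schema = FeatureSchema(
            [FeatureDescriptor(d["name"], d["group"], d["params"])
             for d in doc["schema"]]
        )
        boost = BoostModel.from_json(json.dumps(doc["boost"]))
        return SegmenterModel(RVOI(mask), schema, boost,
                              provenance=doc.get("provenance", {}))


def _check_cohort(cohort: CohortDataset) -> None:
    shapes = {v.shape for _, v, _ in cohort.subjects}
    if len(shapes) > 1:
        raise InvalidArgumentError(f"cohort volumes on mixed grids: {shapes}")


def assemble_training_set(
    cohort: CohortDataset,
    m: int,
    rng: np.random.Generator,
    dilation_kernel: Tuple[int, int, int] = (2, 2, 2),
    schema: Optional[FeatureSchema] = None,
    max_voxels_per_subject: Optional[int] = None,
    glcm_levels: int = 8,
) -> Tuple[np.ndarray, np.ndarray, RVOI, FeatureSchema, List[int]]:
    """Build (X, y, rvoi, schema, training subject indices).

    With no voxel subsampling the sample count is exactly
    ``m * |rVOI|``; ``max_voxels_per_subject`` optionally subsamples the
    rVOI voxel list per subject uniformly at random (a desk-scale deviation
    recorded by the caller in model provenance).
    """
    _check_cohort(cohort)
    if not (1 <= m <= len(cohort)):
        raise InvalidArgumentError(f"m={m} out of range for cohort of {len(cohort)}")
    if schema is None:
        schema = default_schema(levels=glcm_levels)
    train_idx = sorted(rng.choice(len(cohort), size=m, replace=False).tolist())
    masks = [cohort.subjects[i][2] for i in train_idx]
    rvoi = build_rvoi(masks, dilation_kernel)
    X_parts, y_parts = [], []
    for i in train_idx:
        _, vol, mask = cohort.subjects[i]
        voxels = rvoi.voxels
        if max_voxels_per_subject is not None and max_voxels_per_subject < len(voxels):
            sel = np.sort(
                rng.choice(len(voxels), size=max_voxels_per_subject, replace=False)
            )
            voxels = voxels[sel]
        X_parts.append(extract_feature_matrix(vol, voxels, schema, levels=glcm_levels))
        lab = np.where(mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]], 1, -1)
        y_parts.append(lab)
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts)
    return X, y, rvoi, schema, train_idx


def train_segmenter(
    cohort: CohortDataset,
    m: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    T: int = 150,
    N: float = 0.5,
    eta: float = 0.1,
    max_depth: int = 3,
    rus_enabled: bool = True,
    dilation_kernel: Tuple[int, int, int] = (2, 2, 2),
    max_voxels_per_subject: Optional[int] = None,
    glcm_levels: int = 8,
    eps_floor: float = 1e-10,
    round_log: Optional[list] = None,
) -> SegmenterModel:
    """Train a full segmenter on ``m`` randomly chosen cohort subjects."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X, y, rvoi, schema, train_idx = assemble_training_set(
        cohort, m, rng,
        dilation_kernel=dilation_kernel,
        max_voxels_per_subject=max_voxels_per_subject,
        glcm_levels=glcm_levels,
    )
    boost = train_boost(
        X, y, T=T, N=N, eta=eta, max_depth=max_depth,
        rus_enabled=rus_enabled, rng=rng, eps_floor=eps_floor,
        seed=seed, round_log=round_log,
    )
    boost.schema_hash = schema.hash()
    size, minority_pct = rvoi_stats(rvoi, [cohort.subjects[i][2] for i in train_idx])
    prov = {
        "training_subjects": [cohort.subjects[i][0] for i in train_idx],
        "m": m,
        "seed": seed,
        "side": cohort.side,
        "rvoi_size": size,
        "rvoi_minority_pct": minority_pct,
        "max_voxels_per_subject": max_voxels_per_subject,
        "dilation_kernel": list(dilation_kernel),
        "glcm_levels": glcm_levels,
    }
    return SegmenterModel(rvoi, schema, boost, provenance=prov)


def segment_image(model: SegmenterModel, volume: np.ndarray,
                  glcm_levels: Optional[int] = None) -> np.ndarray:
    """Segment a co-registered VOI volume; the prediction never leaves the rVOI."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != model.rvoi.mask.shape:
        raise InvalidArgumentError(
            f"volume grid {volume.shape} != model rVOI grid {model.rvoi.mask.shape}"
        )
    levels = glcm_levels or model.provenance.get("glcm_levels", 8)
    X = extract_feature_matrix(volume, model.rvoi.voxels, model.schema, levels=levels)
    labels = rusboost.predict_label_batch(model.boost, X)
    out = np.zeros(volume.shape, dtype=np.uint8)
    vox = model.rvoi.voxels[labels == 1]
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
    return out


def cross_validate(
    cohort: CohortDataset,
    m: int,
    n_rounds: int = 10,
    seed: Optional[int] = None,
    **train_kwargs,
) -> pd.DataFrame:
    """Repeated random-subsampling CV: ``n_rounds`` fresh m/(rest) partitions.

    Returns a tidy frame with one row per metric (plus rVOI size), columns
    (metric, mean, sd, m, side).  Within a round, metrics are averaged over
    the held-out subjects; mean/sd are taken across rounds.
    """
    if not (1 <= m < len(cohort)):
        raise InvalidArgumentError("need 1 <= m < cohort size for cross-validation")
    if n_rounds < 1:
        raise InvalidArgumentError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    per_round: Dict[str, List[float]] = {k: [] for k in METRIC_NAMES}
    rvoi_sizes: List[float] = []
    for _ in range(n_rounds):
        round_rng = np.random.default_rng(rng.integers(2**31))
        model = train_segmenter(cohort, m, rng=round_rng, **train_kwargs)
        train_ids = set(model.provenance["training_subjects"])
        test_subjects = [s for s in cohort.subjects if s[0] not in train_ids]
        scores: Dict[str, List[float]] = {k: [] for k in METRIC_NAMES}
        for _, vol, mask in test_subjects:
            rep = overlap_metrics(segment_image(model, vol), mask)
            for k in METRIC_NAMES:
                scores[k].append(getattr(rep, k if k != "relative_overlap"
                                         else "relative_overlap"))
        for k in METRIC_NAMES:
            per_round[k].append(float(np.mean(scores[k])))
        rvoi_sizes.append(float(model.provenance["rvoi_size"]))
    rows = [
        {"metric": k, "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=0)),
         "m": m, "side": cohort.side}
        for k, v in per_round.items()
    ]
    rows.append({"metric": "rvoi_size", "mean": float(np.mean(rvoi_sizes)),
                 "sd": float(np.std(rvoi_sizes, ddof=0)), "m": m,
                 "side": cohort.side})
    return pd.DataFrame(rows)
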