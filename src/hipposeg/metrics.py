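"""Segmentation overlap metrics and volume-agreement statistics.

Overlap between a predicted and a manual binary mask is summarised by four
standard set metrics,

    Dice = 2|A∩B| / (|A| + |B|)        Precision = TP / (TP + FP)
    RO   = |A∩B| / |A∪B|  (Jaccard)    Recall    = TP / (TP + FN)

linked by the identity Dice = 2*RO / (1 + RO).  Volume agreement across a
cohort is assessed with the Pearson correlation and an OLS fit of manual on
automated volumes, plus an exact paired two-sided sign test of the
zero-median null on the volume differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

__all__ = ["MetricsReport", "overlap_metrics", "volume_agreement", "sign_test"]


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    precision: float
    recall: float
    relative_overlap: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "precision": self.precision,
            "recall": self.recall,
            "relative_overlap": self.relative_overlap,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def overlap_metrics(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Voxel-overlap metrics of a predicted mask against a manual mask.

    Conventions: precision = 0 for an empty prediction; Dice and RO are 0
    when the intersection is empty.  An empty truth mask is rejected.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise InvalidArgumentError(
            f"mask grid mismatch: {pred.shape} vs {truth.shape}"
        )
    if not truth.any():
        raise InvalidArgumentError("truth mask is empty")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    union = tp + fp + fn
    dice = 2.0 * tp / (2 * tp + fp + fn) if tp else 0.0
    ro = tp / union if tp else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn)
    return MetricsReport(dice, precision, recall, ro, tp, fp, fn, tn)


def volume_agreement(auto_volumes: Sequence[float],
                     manual_volumes: Sequence[float]
                     ) -> Tuple[float, float, float]:
    """(Pearson r, slope, intercept) of manual regressed on automated volumes."""
    a = np.asarray(auto_volumes, dtype=float)
    m = np.asarray(manual_volumes, dtype=float)
    if a.shape != m.shape or a.ndim != 1 or a.size < 3:
        raise InvalidArgumentError("need two equal-length volume lists of size >= 3")
    if np.var(a) == 0 or np.var(m) == 0:
        raise InvalidArgumentError("volume lists must have nonzero variance")
    r = float(stats.pearsonr(a, m).statistic)
    fit = stats.linregress(a, m)
    return r, float(fit.slope), float(fit.intercept)


def sign_test(differences: Sequence[float]) -> float:
    """Exact two-sided sign test p-value for a zero-median null.

    Zero differences are dropped (the classical procedure); the p-value is
    the exact two-sided binomial tail probability, at success probability
    1/2, of the observed count of positive signs.
    """
    d = np.asarray(differences, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise InvalidArgumentError("all differences are zero; sign test undefined")
    k = int(np.count_nonzero(nz > 0))
    return float(stats.binomtest(k, nz.size, 0.5, alternative="two-sided").pvalue)
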