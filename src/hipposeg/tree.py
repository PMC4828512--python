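"""Weighted, depth-limited CART-style decision tree weak learner.

The tree is the confidence-rated weak hypothesis of the boosting loop:
``h(x, +1)`` is the weighted fraction of positive examples in the leaf that
``x`` falls into, and ``h(x, -1) = 1 - h(x, +1)``, so the complementarity
invariant ``h(x,+1) + h(x,-1) = 1`` holds by construction.

Splits are found by exhaustive search over midpoint thresholds between
consecutive distinct feature values, minimising the weighted Gini impurity of
the two children.  Ties are broken deterministically: lowest feature index
first, then lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["TreeNode", "DecisionTreeHypothesis", "fit_weak_learner"]

# A split must reduce the weighted Gini cost by more than this to be accepted.
_MIN_GAIN = 1e-12


@dataclass
class TreeNode:
    """A node of the decision tree.

    Internal nodes carry ``feature``/``threshold`` (go left iff
    ``x[feature] <= threshold``); leaves carry ``p_pos``, the weighted
    fraction of +1 examples that reached the leaf during training.
    """

    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    p_pos: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"p_pos": float(self.p_pos)}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "TreeNode":
        if "p_pos" in d:
            return TreeNode(p_pos=float(d["p_pos"]))
        return TreeNode(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=TreeNode.from_dict(d["left"]),
            right=TreeNode.from_dict(d["right"]),
        )


class DecisionTreeHypothesis:
    """Confidence-rated hypothesis ``h: X x Y -> [0, 1]`` backed by a tree."""

    def __init__(self, root: TreeNode, n_features: int):
        self.root = root
        self.n_features = int(n_features)

    # -- evaluation ---------------------------------------------------------

    def confidence_pos(self, X: np.ndarray) -> np.ndarray:
        """Vectorised ``h(x, +1)`` for a batch of feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise InvalidArgumentError(
                f"feature vector length {X.shape[1]} != schema size {self.n_features}"
            )
        out = np.empty(X.shape[0], dtype=float)
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf:
                out[idx] = node.p_pos
                continue
            go_left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out

    def evaluate(self, x: np.ndarray, label: int) -> float:
        """``h(x, label)`` for a single feature vector."""
        p = float(self.confidence_pos(np.asarray(x, dtype=float))[0])
        return p if label == 1 else 1.0 - p

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {"n_features": self.n_features, "root": self.root.to_dict()}

    @staticmethod
    def from_dict(d: dict) -> "DecisionTreeHypothesis":
        return DecisionTreeHypothesis(TreeNode.from_dict(d["root"]), d["n_features"])


def _gini_cost(wp: float, wn: float) -> float:
    # weighted Gini "cost" W * (1 - p_pos^2 - p_neg^2) == W - (wp^2 + wn^2)/W
    w = wp + wn
    if w <= 0.0:
        return 0.0
    return w - (wp * wp + wn * wn) / w


def _split_scan(XT, wp, wn, orderT, tp, tn):
    """Single sequential pass per feature over presorted rows.

    ``XT`` is the feature-major (d, n_global) data matrix; ``orderT[f]``
    lists the node's global row indices in ascending order of feature f.
    For each feature the scan accumulates left-side class weights and
    records the best valid midpoint split by the weighted-Gini gain
    ``(lp^2 + ln^2)/wl + (rp^2 + rn^2)/wr`` (maximising this is
    equivalent to minimising the weighted Gini cost).  Returns the
    per-feature best gain and split position (-1 when no valid split).
    """
    d, k = orderT.shape
    best_gain = np.full(d, -np.inf)
    best_pos = np.full(d, -1, dtype=np.int64)
    tw = tp + tn
    for f in range(d):
        lp = 0.0
        ln = 0.0
        xrow = XT[f]
        orow = orderT[f]
        nxt = xrow[orow[0]]
        for i in range(k - 1):
            r = orow[i]
            cur = nxt
            nxt = xrow[orow[i + 1]]
            lp += wp[r]
            ln += wn[r]
            if cur < nxt:
                wl = lp + ln
                wr = tw - wl
                if wl > 0.0 and wr > 0.0:
                    rp = tp - lp
                    rn = tn - ln
                    g = (lp * lp + ln * ln) / wl + (rp * rp + rn * rn) / wr
                    if g > best_gain[f]:
                        best_gain[f] = g
                        best_pos[f] = i
    return best_gain, best_pos


try:  # optional JIT; the pure-numpy scan above is the reference behaviour
    from numba import njit as _njit

    _split_scan_jit = _njit(cache=True, nogil=True)(_split_scan)
except Exception:  # pragma: no cover - numba unavailable
    _split_scan_jit = None


def _best_split(XT: np.ndarray, wp: np.ndarray, wn: np.ndarray,
                orderT: np.ndarray):
    """Exhaustive weighted-Gini split search over all features.

    ``XT`` is the (d, n_global) feature-major data matrix; ``orderT``
    holds, per feature row, the node's global row indices sorted by that
    feature (presorted once at the root and filtered down the recursion).
    Returns ``(feature, threshold, cost)`` of the best valid split, or
    None.  wp/wn are the global per-example weights attributed to the
    +1 / -1 class (one of the two is zero for every example).
    """
    d, k = orderT.shape
    if k < 2:
        return None
    sel = orderT[0]
    tp = float(wp[sel].sum())
    tn = float(wn[sel].sum())
    scan = _split_scan_jit if _split_scan_jit is not None else _split_scan
    best_gain, best_pos = scan(XT, wp, wn, orderT, tp, tn)
    f = int(np.argmax(best_gain))          # ties -> lowest feature index
    if not np.isfinite(best_gain[f]):
        return None
    i = int(best_pos[f])                   # first best -> lowest threshold
    thr = 0.5 * (XT[f, orderT[f, i]] + XT[f, orderT[f, i + 1]])
    return f, float(thr), float(tp + tn - best_gain[f])


def _filter_order(orderT: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Restrict per-feature sorted row indices to a membership subset."""
    keep = member[orderT]                     # (d, n) bool
    k = int(keep[0].sum())
    return np.ascontiguousarray(orderT[keep].reshape(orderT.shape[0], k))


def _grow(X, XT, wp, wn, orderT, member, depth_left) -> TreeNode:
    swp = float(wp[member].sum())
    swn = float(wn[member].sum())
    total = swp + swn
    leaf = TreeNode(p_pos=(swp / total) if total > 0 else 0.5)
    if depth_left == 0 or swp == 0.0 or swn == 0.0:
        return leaf
    found = _best_split(XT, wp, wn, orderT)
    if found is None:
        return leaf
    f, thr, cost = found
    if cost >= _gini_cost(swp, swn) - _MIN_GAIN:
        return leaf
    go_left = X[:, f] <= thr
    left_member = member & go_left
    right_member = member & ~go_left
    return TreeNode(
        feature=f,
        threshold=thr,
        left=_grow(X, XT, wp, wn, _filter_order(orderT, left_member),
                   left_member, depth_left - 1),
        right=_grow(X, XT, wp, wn, _filter_order(orderT, right_member),
                    right_member, depth_left - 1),
    )


def fit_weak_learner(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    max_depth: int = 3,
) -> DecisionTreeHypothesis:
    """Fit a depth-limited weighted decision tree on ``(X, y, weights)``.

    Parameters
    ----------
    X : (m, d) float array of feature rows.
    y : (m,) array with labels in {-1, +1}.
    weights : (m,) nonnegative example weights (the boosting distribution
        restricted to this training subset).
    max_depth : maximum number of split levels (1 = decision stump).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    weights = np.asarray(weights, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidArgumentError("empty dataset")
    if y.shape[0] != X.shape[0] or weights.shape[0] != X.shape[0]:
        raise InvalidArgumentError("weights/labels misaligned with dataset")
    if max_depth < 1:
        raise InvalidArgumentError("max_depth must be >= 1")
    if np.any(weights < 0):
        raise InvalidArgumentError("negative weights")
    wp = np.where(y > 0, weights, 0.0)
    wn = np.where(y < 0, weights, 0.0)
    XT = np.ascontiguousarray(X.T)
    orderT = np.ascontiguousarray(np.argsort(X, axis=0, kind="stable").T.astype(np.int32))
    member = np.ones(X.shape[0], dtype=bool)
    root = _grow(X, XT, wp, wn, orderT, member, max_depth)
    return DecisionTreeHypothesis(root, X.shape[1])
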