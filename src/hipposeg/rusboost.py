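"""Boosting with random undersampling (RUSBoost) for imbalanced voxel data.

The classifier is AdaBoost.M2-style confidence-rated boosting in which every
round first rebalances the working set by randomly discarding majority-class
(background) examples until a target minority fraction ``N`` is reached, then
fits a weak tree hypothesis on the balanced subset, while the pseudo-loss,
the round weight ``alpha_t = eps_t / (1 - eps_t)`` and the multiplicative
weight update are all computed on the *full* training set.  Disabling the
undersampling step (``rus_enabled=False``) yields the plain Adaboost
baseline run through the identical loop.

Labels are ``+1`` for hippocampus (the minority class) and ``-1`` for
background.  The final ensemble predicts

    H(x) = argmax_y  sum_t  h_t(x, y) * log(1 / alpha_t)

with ties resolved toward the background class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidArgumentError, InvalidDatasetError
from .tree import DecisionTreeHypothesis, fit_weak_learner

__all__ = [
    "BoostModel",
    "initialize_weights",
    "random_undersample",
    "fit_weak_learner",
    "pseudo_loss",
    "alpha_from_loss",
    "update_weights",
    "train_boost",
    "predict_scores",
    "predict_scores_batch",
    "predict_label",
    "predict_label_batch",
]

_WEIGHT_TOL = 1e-9


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise InvalidArgumentError("labels must be in {-1, +1}")
    return y.astype(int)


def initialize_weights(m: int) -> np.ndarray:
    """Uniform starting distribution ``D_1(i) = 1/m``."""
    if not isinstance(m, (int, np.integer)) or m <= 0:
        raise InvalidArgumentError(f"number of examples must be a positive integer, got {m!r}")
    return np.full(int(m), 1.0 / m, dtype=float)


def random_undersample(
    y: np.ndarray,
    weights: np.ndarray,
    minority_fraction: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Randomly drop majority (-1) examples until the minority (+1) share is N.

    Returns ``(indices, sub_weights)``: the retained example indices in
    original dataset order and their weights renormalised to sum to 1.  All
    minority examples are always retained; if the majority count is already
    at or below the target the dataset is returned unchanged.
    """
    y = _check_labels(y)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != y.shape:
        raise InvalidArgumentError("weights misaligned with dataset")
    if not (0.0 < minority_fraction <= 1.0):
        raise InvalidArgumentError(f"minority fraction must be in (0, 1], got {minority_fraction}")
    min_idx = np.flatnonzero(y == 1)
    maj_idx = np.flatnonzero(y == -1)
    if min_idx.size == 0:
        raise InvalidDatasetError("dataset contains no minority (+1) examples")
    n_min = min_idx.size
    target_maj = int(round(n_min * (1.0 - minority_fraction) / minority_fraction))
    if maj_idx.size > target_maj:
        keep_maj = rng.choice(maj_idx, size=target_maj, replace=False)
        idx = np.sort(np.concatenate([min_idx, keep_maj]))
    else:
        idx = np.arange(y.size)
    w = weights[idx]
    total = w.sum()
    if total <= 0:
        # degenerate: all retained weight mass is zero; fall back to uniform
        w = np.full(idx.size, 1.0 / idx.size)
    else:
        w = w / total
    return idx, w


def pseudo_loss(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    hypothesis: DecisionTreeHypothesis,
    half_scaling: bool = True,
) -> float:
    """Pseudo-loss of a confidence-rated hypothesis on the full set.

    eps_t = 1/2 * sum_{(i,y): y != y_i} D_t(i) * (1 - h(x_i, y_i) + h(x_i, y))

    With binary labels and complementary confidences this reduces to
    ``sum_i D_t(i) * (1 - h(x_i, y_i))`` and lies in [0, 1], with the
    uninformative hypothesis ``h ≡ 0.5`` scoring exactly 0.5.
    ``half_scaling=False`` computes the literal unhalved sum instead
    (range [0, 2]).
    """
    y = _check_labels(y)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != y.shape[0] or np.asarray(X).shape[0] != y.shape[0]:
        raise InvalidArgumentError("weights misaligned with dataset")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise InvalidArgumentError("weights must be normalized")
    p = hypothesis.confidence_pos(X)
    h_correct = np.where(y == 1, p, 1.0 - p)
    h_wrong = 1.0 - h_correct
    eps = float(np.sum(weights * (1.0 - h_correct + h_wrong)))
    return 0.5 * eps if half_scaling else eps


def alpha_from_loss(eps: float, eps_floor: float = 1e-10) -> float:
    """Round weight parameter ``alpha = eps / (1 - eps)`` with loss flooring.

    The floor keeps ``log(1/alpha)`` finite when a round is perfect
    (eps = 0).  alpha is monotone increasing in eps and ``alpha <= 1``
    exactly when ``eps <= 1/2``.
    """
    if not (0.0 <= eps < 1.0):
        raise InvalidArgumentError(f"pseudo-loss must be in [0, 1), got {eps}")
    e = max(float(eps), float(eps_floor))
    return e / (1.0 - e)


def update_weights(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    hypothesis: DecisionTreeHypothesis,
    alpha: float,
    eta: float = 1.0,
) -> np.ndarray:
    """Multiplicative weight update followed by renormalisation.

    Each weight is multiplied by ``alpha ** (eta * (1 + h(x_i,y_i) -
    h(x_i, y != y_i)) / 2)``; with complementary confidences the exponent is
    ``eta * h(x_i, y_i)``, so with hard 0/1 confidences and ``eta = 1`` the
    update is the piecewise form: correctly labeled examples are scaled by
    alpha, misclassified ones are left unchanged (then all renormalised).
    The learning rate ``eta`` shrinks the update exponent only; it does not
    enter the prediction weights.
    """
    if alpha <= 0:
        raise InvalidArgumentError(f"alpha must be positive, got {alpha}")
    if not (0.0 < eta <= 1.0):
        raise InvalidArgumentError(f"learning rate must be in (0, 1], got {eta}")
    y = _check_labels(y)
    weights = np.asarray(weights, dtype=float)
    p = hypothesis.confidence_pos(X)
    h_correct = np.where(y == 1, p, 1.0 - p)
    h_wrong = 1.0 - h_correct
    exponent = eta * 0.5 * (1.0 + h_correct - h_wrong)
    new = weights * np.power(alpha, exponent)
    total = new.sum()
    if total <= 0:
        raise InvalidArgumentError("weight update collapsed to zero mass")
    return new / total


@dataclass
class BoostModel:
    """Trained ensemble of confidence-rated tree hypotheses."""

    rounds: List[Tuple[DecisionTreeHypothesis, float]]
    n_rounds_requested: int
    minority_fraction: float
    learning_rate: float
    rus_enabled: bool
    max_depth: int
    n_features: int
    seed: Optional[int] = None
    schema_hash: Optional[str] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.rounds) > self.n_rounds_requested:
            raise InvalidArgumentError("more rounds stored than requested")
        for _, a in self.rounds:
            if not (0.0 < a <= 1.0):
                raise InvalidArgumentError(f"round alpha {a} outside (0, 1]")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "hipposeg-boost-model",
            "version": 1,
            "T": self.n_rounds_requested,
            "N": self.minority_fraction,
            "eta": self.learning_rate,
            "rus_enabled": self.rus_enabled,
            "max_depth": self.max_depth,
            "n_features": self.n_features,
            "seed": self.seed,
            "schema_hash": self.schema_hash,
            "provenance": self.provenance,
            "rounds": [
                {"alpha": float(a), "tree": h.to_dict()} for h, a in self.rounds
            ],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @staticmethod
    def from_json(text: str) -> "BoostModel":
        doc = json.loads(text)
        if doc.get("format") != "hipposeg-boost-model":
            raise InvalidArgumentError("not a hipposeg boost model document")
        rounds = [
            (DecisionTreeHypothesis.from_dict(r["tree"]), float(r["alpha"]))
            for r in doc["rounds"]
        ]
        return BoostModel(
            rounds=rounds,
            n_rounds_requested=doc["T"],
            minority_fraction=doc["N"],
            learning_rate=doc["eta"],
            rus_enabled=doc["rus_enabled"],
            max_depth=doc["max_depth"],
            n_features=doc["n_features"],
            seed=doc.get("seed"),
            schema_hash=doc.get("schema_hash"),
            provenance=doc.get("provenance", {}),
        )


def train_boost(
    X: np.ndarray,
    y: np.ndarray,
    T: int = 150,
    N: float = 0.5,
    eta: float = 0.1,
    max_depth: int = 3,
    rus_enabled: bool = True,
    rng: Optional[np.random.Generator] = None,
    eps_floor: float = 1e-10,
    max_retries: int = 3,
    half_scaling: bool = True,
    seed: Optional[int] = None,
    round_log: Optional[list] = None,
) -> BoostModel:
    """Run the full boosting loop for up to ``T`` rounds.

    Per round: (optionally) undersample the majority class to minority
    fraction ``N``, fit the weak tree on the subset with the renormalised
    sub-distribution, evaluate the pseudo-loss on the full dataset under the
    current distribution ``D_t``, derive ``alpha_t`` and update/renormalise
    the weights.  A round whose pseudo-loss reaches 0.5 is retried with a
    fresh undersample up to ``max_retries`` times; if it still fails, the
    loop stops early and returns the rounds accumulated so far.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidArgumentError("X/y misaligned")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise InvalidDatasetError("training set must contain both classes")
    if T < 1:
        raise InvalidArgumentError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    m = y.size
    D = initialize_weights(m)
    rounds: List[Tuple[DecisionTreeHypothesis, float]] = []
    for t in range(T):
        h = eps = None
        attempts = (max_retries + 1) if rus_enabled else 1
        for _ in range(attempts):
            if rus_enabled:
                idx, D_sub = random_undersample(y, D, N, rng)
            else:
                idx, D_sub = np.arange(m), D
            h = fit_weak_learner(X[idx], y[idx], D_sub, max_depth=max_depth)
            eps = pseudo_loss(X, y, D, h, half_scaling=half_scaling)
            if eps < 0.5:
                break
        if eps is None or eps >= 0.5:
            break  # early termination: no useful weak hypothesis found
        alpha = alpha_from_loss(eps, eps_floor)
        D = update_weights(X, y, D, h, alpha, eta)
        rounds.append((h, alpha))
        if round_log is not None:
            round_log.append({"round": t + 1, "pseudo_loss": eps, "alpha": alpha})
    if not rounds:
        raise InvalidDatasetError(
            "boosting terminated with zero usable rounds (pseudo-loss >= 0.5)"
        )
    return BoostModel(
        rounds=rounds,
        n_rounds_requested=T,
        minority_fraction=N,
        learning_rate=eta,
        rus_enabled=rus_enabled,
        max_depth=max_depth,
        n_features=X.shape[1],
        seed=seed,
    )


def predict_scores_batch(model: BoostModel, X: np.ndarray) -> np.ndarray:
    """Per-class vote totals ``sum_t h_t(x, y) log(1/alpha_t)``.

    Returns an (n, 2) array with columns (score for +1, score for -1).
    """
    if not model.rounds:
        raise InvalidArgumentError("model has no rounds")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise InvalidArgumentError(
            f"feature vector length {X.shape[1]} != model feature count {model.n_features}"
        )
    s_pos = np.zeros(X.shape[0])
    s_neg = np.zeros(X.shape[0])
    for h, alpha in model.rounds:
        lw = np.log(1.0 / alpha)
        p = h.confidence_pos(X)
        s_pos += p * lw
        s_neg += (1.0 - p) * lw
    return np.column_stack([s_pos, s_neg])


def predict_scores(model: BoostModel, x: np.ndarray) -> Tuple[float, float]:
    """Vote totals for a single feature vector: ``(score_pos, score_neg)``."""
    s = predict_scores_batch(model, np.asarray(x, dtype=float)[None, :])
    return float(s[0, 0]), float(s[0, 1])


def predict_label_batch(model: BoostModel, X: np.ndarray) -> np.ndarray:
    """Argmax labels in {-1, +1}; exact ties go to -1 (background)."""
    s = predict_scores_batch(model, X)
    return np.where(s[:, 0] > s[:, 1], 1, -1)


def predict_label(model: BoostModel, x: np.ndarray) -> int:
    return int(predict_label_batch(model, np.asarray(x, dtype=float)[None, :])[0])
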