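"""Regularized second-order gradient-boosted regression trees with
per-feature monotonic constraints.

This is the computational core of the package, written from first
principles.  Each boosting round fits one regression tree to the current
gradients/hessians of the squared-error objective by exact greedy split
search; leaf weights take the regularized Newton step

    w = −softthreshold(G, α) / (H + λ)

and split quality is the standard second-order gain

    gain = ½·[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ.

Monotonicity (predictions nondecreasing in a +1-flagged feature, here the
temperature column) is enforced in two steps, which together make the
guarantee global rather than per-split: a candidate split on a flagged
column is rejected unless its left-child weight ≤ right-child weight, and
the children of an accepted flagged split inherit weight bounds split at the
midpoint (w_L + w_R)/2 — the left subtree may never produce a leaf above the
midpoint, the right never below it.  A sum of trees each nondecreasing in
the flagged feature is nondecreasing, so the ensemble inherits the property.

Determinism: threshold candidates are midpoints of adjacent distinct sorted
values; gain ties break toward the lowest column index, then the lowest
threshold; row/column subsampling per round m draws from a fresh generator
seeded by (random_state, m).  Two fits with identical inputs and seed are
bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y

from .features import DesignMatrix, FeatureSchema

__all__ = [
    "BoostParams",
    "TreeNode",
    "MonotoneGradientBoostingRegressor",
    "BoostedModel",
    "leaf_weight",
    "split_gain",
    "find_best_split",
    "grow_tree",
    "fit_booster",
    "predict_booster",
    "PUBLISHED_PARAMS",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BoostParams:
    """Hyperparameters of the boosted ensemble."""

    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.05
    subsample: float = 0.7
    colsample_bytree: float = 0.7
    gamma: float = 0.0
    reg_alpha: float = 0.0
    reg_lambda: float = 1.0
    min_child_weight: float = 1.0
    seed: int = 42

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must lie in (0, 1]")
        if not (0 < self.subsample <= 1) or not (0 < self.colsample_bytree <= 1):
            raise ValueError("subsample and colsample_bytree must lie in (0, 1]")
        if self.gamma < 0 or self.reg_alpha < 0 or self.reg_lambda < 0:
            raise ValueError("gamma, reg_alpha and reg_lambda must be nonnegative")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


#: The published optimum for this problem (squared-error objective, exact
#: greedy trees): 300 rounds of depth-4 trees, shrinkage 0.05, 70% row and
#: column sampling, γ=0, α=0, λ=1, min_child_weight=1, seed 42.
PUBLISHED_PARAMS = BoostParams()


@dataclass
class TreeNode:
    """Either an internal split (feature, threshold, children) or a leaf."""

    is_leaf: bool
    weight: float = 0.0
    feature: int = -1
    threshold: float = math.nan
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        self._route(X, np.arange(X.shape[0]), out)
        return out

    def _route(self, X: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[rows] = self.weight
            return
        go_left = X[rows, self.feature] < self.threshold
        self.left._route(X, rows[go_left], out)
        self.right._route(X, rows[~go_left], out)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.weight}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeNode":
        if "leaf" in payload:
            return cls(is_leaf=True, weight=float(payload["leaf"]))
        return cls(is_leaf=False, feature=int(payload["feature"]),
                   threshold=float(payload["threshold"]),
                   left=cls.from_dict(payload["left"]), right=cls.from_dict(payload["right"]))


def _soft_threshold(G, alpha: float):
    return np.where(G > alpha, G - alpha, np.where(G < -alpha, G + alpha, 0.0))


def leaf_weight(G, H, alpha: float = 0.0, lam: float = 1.0,
                lower: float = -np.inf, upper: float = np.inf):
    """Regularized Newton leaf weight, clipped into the monotone bounds."""
    w = -_soft_threshold(np.asarray(G, dtype=float), alpha) / (np.asarray(H, dtype=float) + lam)
    return np.clip(w, lower, upper)


def split_gain(GL, HL, GR, HR, lam: float = 1.0, gamma: float = 0.0):
    """Second-order gain of splitting a node into (L, R), minus the γ penalty."""
    GL, HL = np.asarray(GL, dtype=float), np.asarray(HL, dtype=float)
    GR, HR = np.asarray(GR, dtype=float), np.asarray(HR, dtype=float)
    parent = (GL + GR) ** 2 / (HL + HR + lam)
    return 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - parent) - gamma


@dataclass(frozen=True)
class _Split:
    feature: int
    threshold: float
    gain: float


def find_best_split(X: np.ndarray, g: np.ndarray, h: np.ndarray, rows: np.ndarray,
                    columns: Sequence[int], params: BoostParams,
                    monotone: np.ndarray, lower: float, upper: float) -> _Split | None:
    """Exact greedy search over every (column, boundary) candidate.

    Candidates must leave ≥ min_child_weight hessian mass on each side, have
    strictly positive gain, and — on a +1-flagged column — a left-child
    weight not exceeding the right-child weight (weights evaluated with the
    node's current bounds).  Ties in gain break toward the lowest column
    index, then the lowest threshold.
    """
    best: _Split | None = None
    lam, gamma, alpha = params.reg_lambda, params.gamma, params.reg_alpha
    for j in columns:
        v = X[rows, j]
        order = np.argsort(v, kind="stable")
        vs, gs, hs = v[order], g[rows][order], h[rows][order]
        Gc, Hc = np.cumsum(gs), np.cumsum(hs)
        Gtot, Htot = Gc[-1], Hc[-1]
        distinct = vs[1:] > vs[:-1]
        if not distinct.any():
            continue
        GL, HL = Gc[:-1][distinct], Hc[:-1][distinct]
        GR, HR = Gtot - GL, Htot - HL
        thresholds = 0.5 * (vs[:-1] + vs[1:])[distinct]
        valid = (HL >= params.min_child_weight) & (HR >= params.min_child_weight)
        if monotone[j] == +1:
            wL = leaf_weight(GL, HL, alpha, lam, lower, upper)
            wR = leaf_weight(GR, HR, alpha, lam, lower, upper)
            valid &= wL <= wR
        if not valid.any():
            continue
        gains = split_gain(GL, HL, GR, HR, lam, gamma)
        gains[~valid] = -np.inf
        k = int(np.argmax(gains))  # thresholds ascending → first max = lowest threshold
        if gains[k] > 0 and (best is None or gains[k] > best.gain):
            best = _Split(int(j), float(thresholds[k]), float(gains[k]))
    return best


def grow_tree(X: np.ndarray, g: np.ndarray, h: np.ndarray, rows: np.ndarray,
              params: BoostParams, monotone: np.ndarray,
              columns: Sequence[int] | None = None, depth: int = 0,
              lower: float = -np.inf, upper: float = np.inf) -> TreeNode:
    """Recursively grow one tree on ``rows``, propagating monotone bounds."""
    if columns is None:
        columns = range(X.shape[1])
    lam, alpha = params.reg_lambda, params.reg_alpha

    def leaf() -> TreeNode:
        w = leaf_weight(g[rows].sum(), h[rows].sum(), alpha, lam, lower, upper)
        return TreeNode(is_leaf=True, weight=float(w))

    if depth >= params.max_depth or rows.size < 2:
        return leaf()
    split = find_best_split(X, g, h, rows, columns, params, monotone, lower, upper)
    if split is None:
        return leaf()
    go_left = X[rows, split.feature] < split.threshold
    rows_l, rows_r = rows[go_left], rows[~go_left]
    if rows_l.size == 0 or rows_r.size == 0:
        return leaf()
    low_l, up_l, low_r, up_r = lower, upper, lower, upper
    if monotone[split.feature] == +1:
        wL = leaf_weight(g[rows_l].sum(), h[rows_l].sum(), alpha, lam, lower, upper)
        wR = leaf_weight(g[rows_r].sum(), h[rows_r].sum(), alpha, lam, lower, upper)
        mid = 0.5 * (float(wL) + float(wR))
        up_l, low_r = mid, mid
    return TreeNode(
        is_leaf=False, feature=split.feature, threshold=split.threshold,
        left=grow_tree(X, g, h, rows_l, params, monotone, columns, depth + 1, low_l, up_l),
        right=grow_tree(X, g, h, rows_r, params, monotone, columns, depth + 1, low_r, up_r),
    )


class MonotoneGradientBoostingRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regression trees with monotonic constraints.

    Squared-error objective: per round, gradients are ŷ − y and hessians 1,
    so each tree is a regularized fit to the current residuals.  The base
    score is the training-target mean.  ``monotone_constraints`` is a
    per-feature vector of {0, +1}; predictions are guaranteed nondecreasing
    in every +1 feature.

    Parameters follow the conventional gradient-boosting names
    (``n_estimators``, ``max_depth``, ``learning_rate``, ``subsample``,
    ``colsample_bytree``, ``gamma``, ``reg_alpha``, ``reg_lambda``,
    ``min_child_weight``, ``random_state``).  Defaults are the published
    optimum for the solubility problem.

    Attributes (after ``fit``): ``base_score_``, ``trees_``,
    ``n_features_in_``, ``monotone_``, ``train_score_path_`` (training MSE
    after each round).
    """

    def __init__(self, n_estimators: int = 300, max_depth: int = 4,
                 learning_rate: float = 0.05, subsample: float = 0.7,
                 colsample_bytree: float = 0.7, gamma: float = 0.0,
                 reg_alpha: float = 0.0, reg_lambda: float = 1.0,
                 min_child_weight: float = 1.0, random_state: int = 42,
                 monotone_constraints=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.gamma = gamma
        self.reg_alpha = reg_alpha
        self.reg_lambda = reg_lambda
        self.min_child_weight = min_child_weight
        self.random_state = random_state
        self.monotone_constraints = monotone_constraints

    def _params(self) -> BoostParams:
        return BoostParams(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, subsample=self.subsample,
            colsample_bytree=self.colsample_bytree, gamma=self.gamma,
            reg_alpha=self.reg_alpha, reg_lambda=self.reg_lambda,
            min_child_weight=self.min_child_weight, seed=self.random_state,
        )

    def fit(self, X, y) -> "MonotoneGradientBoostingRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty matrix")
        params = self._params()
        n, p = X.shape
        monotone = (np.zeros(p, dtype=int) if self.monotone_constraints is None
                    else np.asarray(self.monotone_constraints, dtype=int))
        if monotone.shape != (p,):
            raise ValueError("monotone_constraints length must equal the feature count")

        self.base_score_ = float(np.mean(y))
        pred = np.full(n, self.base_score_)
        trees: list[TreeNode] = []
        score_path: list[float] = []
        n_rows = max(1, math.floor(params.subsample * n))
        n_cols = max(1, math.ceil(params.colsample_bytree * p))
        h = np.ones(n)
        for m in range(params.n_estimators):
            g = pred - y
            rng = np.random.default_rng([params.seed, m])  # fresh substream per round
            rows = (np.arange(n) if n_rows == n
                    else np.sort(rng.choice(n, size=n_rows, replace=False)))
            cols = (np.arange(p) if n_cols == p
                    else np.sort(rng.choice(p, size=n_cols, replace=False)))
            tree = grow_tree(X, g, h, rows, params, monotone, columns=cols)
            trees.append(tree)
            pred = pred + params.learning_rate * tree.predict(X)
            score_path.append(float(np.mean((pred - y) ** 2)))
        self.trees_ = trees
        self.monotone_ = monotone
        self.n_features_in_ = p
        self.train_score_path_ = np.array(score_path)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise RuntimeError("model is not fitted")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features_in_}, got {X.shape[1]}")
        out = np.full(X.shape[0], self.base_score_)
        for tree in self.trees_:
            out += self.learning_rate * tree.predict(X)
        return out


# ---------------------------------------------------------------------------
# DesignMatrix-level wrapper with persistence


@dataclass
class BoostedModel:
    """A fitted ensemble bound to the feature schema it was trained with."""

    estimator: MonotoneGradientBoostingRegressor
    schema: FeatureSchema

    @property
    def base_score(self) -> float:
        return self.estimator.base_score_

    @property
    def trees(self) -> list[TreeNode]:
        return self.estimator.trees_

    def predict(self, matrix: DesignMatrix) -> np.ndarray:
        if matrix.schema.digest() != self.schema.digest():
            ours, theirs = set(self.schema.names), set(matrix.schema.names)
            diff = sorted(ours.symmetric_difference(theirs)) or ["<scaler statistics differ>"]
            raise ValueError(f"design-matrix schema does not match the model's; "
                             f"offending column(s): {', '.join(map(str, diff))}")
        return self.estimator.predict(matrix.X)

    def to_dict(self) -> dict:
        est = self.estimator
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "params": {k: v for k, v in est.get_params().items()
                       if k != "monotone_constraints"},
            "monotone_constraints": [int(v) for v in est.monotone_],
            "base_score": est.base_score_,
            "trees": [t.to_dict() for t in est.trees_],
            "schema": self.schema.to_dict(),
            "schema_digest": self.schema.digest(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, payload: dict) -> "BoostedModel":
        schema = FeatureSchema.from_dict(payload["schema"])
        if payload.get("schema_digest") != schema.digest():
            raise ValueError("model file is corrupt: schema digest mismatch")
        est = MonotoneGradientBoostingRegressor(
            **payload["params"], monotone_constraints=payload["monotone_constraints"])
        est.base_score_ = float(payload["base_score"])
        est.trees_ = [TreeNode.from_dict(t) for t in payload["trees"]]
        est.monotone_ = np.asarray(payload["monotone_constraints"], dtype=int)
        est.n_features_in_ = schema.n_columns
        return cls(est, schema)

    @classmethod
    def load(cls, path) -> "BoostedModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_booster(matrix: DesignMatrix, params: BoostParams = PUBLISHED_PARAMS) -> BoostedModel:
    """Train the monotone booster on a design matrix (monotone mask from its schema)."""
    est = MonotoneGradientBoostingRegressor(
        n_estimators=params.n_estimators, max_depth=params.max_depth,
        learning_rate=params.learning_rate, subsample=params.subsample,
        colsample_bytree=params.colsample_bytree, gamma=params.gamma,
        reg_alpha=params.reg_alpha, reg_lambda=params.reg_lambda,
        min_child_weight=params.min_child_weight, random_state=params.seed,
        monotone_constraints=matrix.schema.monotone,
    )
    est.fit(matrix.X, matrix.y)
    return BoostedModel(est, matrix.schema)


def predict_booster(model: BoostedModel, matrix: DesignMatrix) -> np.ndarray:
    """Predicted ln x per row of ``matrix``."""
    return model.predict(matrix)
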