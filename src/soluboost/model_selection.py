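"""Data partitioning and hyperparameter search for solubility modelling.

Splits operate on record keys, so a plan can be generated once and applied
to both a corpus and its design matrix.  Three protocols:

* random stratified hold-out (default in-distribution protocol): within each
  solvent stratum records are sorted by temperature and the test rows are
  drawn by seeded systematic sampling, which keeps the solvent and
  temperature distributions consistent across the two sides;
* leave-one-group-out by solute, solvent or (solute, solvent) pair — the
  external-validation protocol for truly unseen compounds;
* seeded k-fold over matrix rows for cross-validated grid search.

Grid search evaluates the full Cartesian grid with the package's monotone
booster and scores each fold with the "paper"-variant RMSLE on the held-out
fold (lower is better); "best average validation score" therefore means
lowest mean RMSLE.  The scorer is pluggable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .booster import BoostParams, MonotoneGradientBoostingRegressor
from .data_model import Corpus, normalize_name
from .features import DesignMatrix
from .metrics import rmsle_from_log

__all__ = [
    "SplitPlan",
    "GridSearchResult",
    "random_holdout",
    "leave_one_group_out",
    "kfold_indices",
    "grid_search",
]

RowKey = tuple[str, str, float]


@dataclass
class SplitPlan:
    """A train/test partition of a corpus, by record key."""

    train_keys: list[RowKey]
    test_keys: list[RowKey]
    strategy: str  # random80 | loso | losvo | pair-grouped
    seed: int | None = None
    held_group: str | tuple | None = None

    def __post_init__(self):
        train, test = set(self.train_keys), set(self.test_keys)
        if train & test:
            raise ValueError("train and test sets overlap")

    def apply(self, corpus: Corpus) -> tuple[Corpus, Corpus]:
        return corpus.subset(self.train_keys), corpus.subset(self.test_keys)

    def row_indices(self, matrix: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
        train, test = set(self.train_keys), set(self.test_keys)
        tr = np.array([i for i, k in enumerate(matrix.row_keys) if k in train], dtype=int)
        te = np.array([i for i, k in enumerate(matrix.row_keys) if k in test], dtype=int)
        return tr, te


def random_holdout(corpus: Corpus, train_fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified random hold-out.

    Per solvent stratum (sorted by temperature, with ties at equal T broken
    by a seeded shuffle so the sampling period cannot lock onto the solute
    cycle), floor(f·n) rows go to train — at least 1 when the stratum has
    ≥ 2 rows — and the test rows are picked by systematic sampling with a
    seeded random start, spreading them over the temperature range.  A
    stratum of size 1 goes entirely to train, with a warning.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    strata: dict[str, list] = {}
    for rec in corpus.records:
        strata.setdefault(normalize_name(rec.solvent), []).append(rec)
    train_keys: list[RowKey] = []
    test_keys: list[RowKey] = []
    for solvent in sorted(strata):
        tiebreak = rng.permutation(len(strata[solvent]))
        recs = [strata[solvent][i] for i in
                sorted(range(len(strata[solvent])),
                       key=lambda i: (strata[solvent][i].temperature, tiebreak[i]))]
        n = len(recs)
        if n == 1:
            warnings.warn(f"solvent stratum {solvent!r} has a single record; kept in train")
            train_keys.append(recs[0].key)
            continue
        n_train = max(1, math.floor(train_fraction * n))
        n_test = n - n_train
        if n_test == 0:
            train_keys.extend(r.key for r in recs)
            continue
        step = n / n_test
        start = rng.uniform(0, step)
        test_idx = {min(n - 1, math.floor(start + i * step)) for i in range(n_test)}
        for i, rec in enumerate(recs):
            (test_keys if i in test_idx else train_keys).append(rec.key)
    return SplitPlan(train_keys, test_keys, "random80", seed)


def leave_one_group_out(corpus: Corpus, group_by: str, held) -> SplitPlan:
    """Hold out every record of one solute, solvent or (solute, solvent) pair."""
    if group_by not in ("solute", "solvent", "pair"):
        raise ValueError("group_by must be 'solute', 'solvent' or 'pair'")

    def group_of(rec) -> str | tuple:
        if group_by == "solute":
            return normalize_name(rec.solute)
        if group_by == "solvent":
            return normalize_name(rec.solvent)
        return (normalize_name(rec.solute), normalize_name(rec.solvent))

    held_norm = (tuple(normalize_name(h) for h in held) if group_by == "pair"
                 else normalize_name(held))
    groups = {group_of(r) for r in corpus.records}
    if held_norm not in groups:
        raise KeyError(f"no records for held-out {group_by} {held!r}")
    train = [r.key for r in corpus.records if group_of(r) != held_norm]
    test = [r.key for r in corpus.records if group_of(r) == held_norm]
    strategy = {"solute": "loso", "solvent": "losvo", "pair": "pair-grouped"}[group_by]
    return SplitPlan(train, test, strategy, held_group=held_norm)


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint seeded folds covering range(n), sizes differing by ≤ 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    perm = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(perm, k)]


@dataclass
class GridSearchResult:
    """Full grid-search table plus the winning combination."""

    table: pd.DataFrame  # one row per combination: params, fold scores, mean
    best_params: dict
    best_score: float
    grid: dict = field(default_factory=dict)

    def write(self, path, header_comments=()) -> None:
        lines = [f"# {c}" for c in header_comments]
        lines.append(self.table.to_csv(index=False).rstrip("\n"))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


#: Default search grid: brackets the published optimum.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 4, 6],
    "learning_rate": [0.05, 0.1],
    "subsample": [0.7, 1.0],
    "colsample_bytree": [0.7, 1.0],
}


def grid_search(matrix: DesignMatrix, grid: Mapping[str, Sequence] | None = None,
                k: int = 5, seed: int = 0,
                scorer: Callable[[np.ndarray, np.ndarray], float] | None = None,
                base_params: BoostParams | None = None) -> GridSearchResult:
    """Exhaustive grid search scored by k-fold cross-validation.

    Every combination of the grid (iterated in insertion order, so the
    result is deterministic) trains the monotone booster on k−1 folds and is
    scored on the held-out fold; default scorer is the "paper" RMSLE on ln x
    (lower is better).  Ties go to the earlier combination.
    """
    grid = dict(grid if grid is not None else DEFAULT_GRID)
    if not grid:
        raise ValueError("grid must be non-empty")
    if scorer is None:
        scorer = lambda y_true, y_pred: rmsle_from_log(y_true, y_pred, "paper")
    base = base_params or BoostParams()
    folds = kfold_indices(len(matrix), k, seed)
    all_rows = np.arange(len(matrix))
    rows = []
    best_idx, best_mean = -1, np.inf
    names = list(grid)
    for combo_idx, values in enumerate(itertools.product(*(grid[n] for n in names))):
        combo = dict(zip(names, values))
        fold_scores = []
        for fold in folds:
            mask = np.ones(len(matrix), dtype=bool)
            mask[fold] = False
            tr = all_rows[mask]
            est = MonotoneGradientBoostingRegressor(
                n_estimators=int(combo.get("n_estimators", base.n_estimators)),
                max_depth=int(combo.get("max_depth", base.max_depth)),
                learning_rate=float(combo.get("learning_rate", base.learning_rate)),
                subsample=float(combo.get("subsample", base.subsample)),
                colsample_bytree=float(combo.get("colsample_bytree", base.colsample_bytree)),
                gamma=float(combo.get("gamma", base.gamma)),
                reg_alpha=float(combo.get("reg_alpha", base.reg_alpha)),
                reg_lambda=float(combo.get("reg_lambda", base.reg_lambda)),
                min_child_weight=float(combo.get("min_child_weight", base.min_child_weight)),
                random_state=base.seed,
                monotone_constraints=matrix.schema.monotone,
            )
            est.fit(matrix.X[tr], matrix.y[tr])
            fold_scores.append(scorer(matrix.y[fold], est.predict(matrix.X[fold])))
        mean_score = float(np.mean(fold_scores))
        rows.append({**combo,
                     **{f"fold{i}_score": s for i, s in enumerate(fold_scores)},
                     "mean_score": mean_score})
        if mean_score < best_mean:  # strict: ties keep the earlier combination
            best_mean, best_idx = mean_score, combo_idx
    table = pd.DataFrame(rows)
    best = {n: table.iloc[best_idx][n] for n in names}
    return GridSearchResult(table=table, best_params=best, best_score=best_mean, grid=grid)
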