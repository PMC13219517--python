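import itertools

import numpy as np
import pytest

from soluboost.booster import (
    BoostedModel,
    BoostParams,
    MonotoneGradientBoostingRegressor,
    TreeNode,
    find_best_split,
    fit_booster,
    grow_tree,
    leaf_weight,
    predict_booster,
    split_gain,
)
from soluboost.features import build_design_matrix


@pytest.mark.parametrize(
    "G, H, alpha, lam, bounds, expected",
    [
        (2.0, 3.0, 0.0, 1.0, (-np.inf, np.inf), -0.5),
        (0.0, 3.0, 0.0, 1.0, (-np.inf, np.inf), 0.0),
        (2.0, 3.0, 5.0, 1.0, (-np.inf, np.inf), 0.0),   # L1 zeroes small gradients
        (2.0, 3.0, 0.0, 1.0, (-0.2, np.inf), -0.2),      # clipped into bounds
        (-4.0, 1.0, 1.0, 0.0, (-np.inf, np.inf), 3.0),   # soft threshold from below
    ],
)
def test_leaf_weight(G, H, alpha, lam, bounds, expected):
    assert leaf_weight(G, H, alpha, lam, *bounds) == pytest.approx(expected)


@pytest.mark.parametrize(
    "GL, HL, GR, HR, lam, gamma, expected",
    [
        (-2.0, 1.0, 2.0, 1.0, 0.0, 0.0, 4.0),
        (-2.0, 1.0, 2.0, 1.0, 0.0, 4.0, 0.0),
        (1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0),  # identical children: no gain
    ],
)
def test_split_gain(GL, HL, GR, HR, lam, gamma, expected):
    assert split_gain(GL, HL, GR, HR, lam, gamma) == pytest.approx(expected)


def _toy(lam=0.0):
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    g = np.array([-1.0, -1.0, 1.0, 1.0])
    h = np.ones(4)
    params = BoostParams(reg_lambda=lam, min_child_weight=1.0)
    return X, g, h, params


def test_find_best_split_toy():
    X, g, h, params = _toy()
    best = find_best_split(X, g, h, np.arange(4), [0], params,
                           np.zeros(1, int), -np.inf, np.inf)
    assert best.feature == 0 and best.threshold == 2.5
    assert best.gain == pytest.approx(2.0)


def test_find_best_split_monotone_rejects_decreasing_pattern():
    X, _, h, params = _toy()
    g = np.array([-1.0, -1.0, 1.0, 1.0])  # leaf weights -G/H = (1, -1): decreasing
    best = find_best_split(X, g, h, np.arange(4), [0], params,
                           np.ones(1, int), -np.inf, np.inf)
    assert best is None


def test_find_best_split_min_child_weight_infeasible():
    X, g, h, _ = _toy()
    params = BoostParams(min_child_weight=3.0)
    best = find_best_split(X, g, h, np.arange(4), [0], params,
                           np.zeros(1, int), -np.inf, np.inf)
    assert best is None


def _exhaustive_best(X, g, h, params, monotone, lower, upper):
    """Independent oracle: enumerate every (column, boundary) candidate."""
    best = None
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2
            left = X[:, j] < thr
            GL, HL = g[left].sum(), h[left].sum()
            GR, HR = g[~left].sum(), h[~left].sum()
            if HL < params.min_child_weight or HR < params.min_child_weight:
                continue
            if monotone[j] == 1:
                wL = leaf_weight(GL, HL, params.reg_alpha, params.reg_lambda, lower, upper)
                wR = leaf_weight(GR, HR, params.reg_alpha, params.reg_lambda, lower, upper)
                if wL > wR:
                    continue
            gain = float(split_gain(GL, HL, GR, HR, params.reg_lambda, params.gamma))
            if gain > 0 and (best is None or gain > best[2] + 1e-12):
                best = (j, thr, gain)
    return best


@pytest.mark.parametrize("constrained", [False, True])
def test_split_search_matches_exhaustive_enumeration(rng, constrained):
    params = BoostParams(min_child_weight=1.0, reg_lambda=1.0, gamma=0.1)
    for _ in range(60):
        n = int(rng.integers(2, 13))
        p = int(rng.integers(1, 4))
        X = np.round(rng.normal(size=(n, p)), 1)  # rounding forces ties
        g = rng.normal(size=n)
        h = np.abs(rng.normal(size=n)) + 0.5
        monotone = np.zeros(p, int)
        if constrained:
            monotone[int(rng.integers(p))] = 1
        ours = find_best_split(X, g, h, np.arange(n), range(p), params,
                               monotone, -np.inf, np.inf)
        oracle = _exhaustive_best(X, g, h, params, monotone, -np.inf, np.inf)
        if oracle is None:
            assert ours is None
        else:
            assert ours.gain == pytest.approx(oracle[2])


def test_grow_tree_constant_gradients_single_leaf():
    X = np.array([[1.0], [2.0], [3.0]])
    g = np.full(3, 2.0)
    h = np.ones(3)
    params = BoostParams(reg_lambda=1.0)
    tree = grow_tree(X, g, h, np.arange(3), params, np.zeros(1, int))
    assert tree.is_leaf
    assert tree.weight == pytest.approx(-6.0 / 4.0)  # -G/(H+λ)


def test_grow_tree_depth1_stump_weights():
    X, g, h, _ = _toy()
    params = BoostParams(max_depth=1, reg_lambda=0.0)
    tree = grow_tree(X, g, h, np.arange(4), params, np.zeros(1, int))
    assert not tree.is_leaf and tree.threshold == 2.5
    assert tree.left.weight == pytest.approx(1.0)
    assert tree.right.weight == pytest.approx(-1.0)


def test_grown_tree_monotone_via_bound_propagation(rng):
    params = BoostParams(max_depth=4, reg_lambda=1.0)
    for _ in range(20):
        n = int(rng.integers(8, 40))
        X = rng.normal(size=(n, 3))
        g = rng.normal(size=n)
        h = np.ones(n)
        tree = grow_tree(X, g, h, np.arange(n), params, np.array([1, 0, 0]))
        base = rng.normal(size=(5, 3))
        grid = np.sort(rng.normal(size=15))
        for row in base:
            probes = np.tile(row, (15, 1))
            probes[:, 0] = grid
            out = tree.predict(probes)
            assert np.all(np.diff(out) >= -1e-12)


def test_fit_constant_target_returns_constant(default_corpus):
    matrix = build_design_matrix(default_corpus)
    y = np.full(len(matrix), -2.5)
    est = MonotoneGradientBoostingRegressor(n_estimators=5).fit(matrix.X, y)
    np.testing.assert_allclose(est.predict(matrix.X), -2.5)
    for tree in est.trees_:
        assert tree.is_leaf and tree.weight == 0.0


def test_single_round_stump_fit_equals_leaf_means():
    X, _, _, _ = _toy()
    y = np.array([3.0, 3.0, 7.0, 9.0])
    est = MonotoneGradientBoostingRegressor(
        n_estimators=1, max_depth=1, learning_rate=1.0, subsample=1.0,
        colsample_bytree=1.0, reg_lambda=0.0).fit(X, y)
    np.testing.assert_allclose(est.predict(X), [3.0, 3.0, 8.0, 8.0])


def test_fit_is_deterministic(default_corpus):
    matrix = build_design_matrix(default_corpus)
    kw = dict(n_estimators=20, random_state=42, monotone_constraints=matrix.schema.monotone)
    a = MonotoneGradientBoostingRegressor(**kw).fit(matrix.X, matrix.y)
    b = MonotoneGradientBoostingRegressor(**kw).fit(matrix.X, matrix.y)
    assert [t.to_dict() for t in a.trees_] == [t.to_dict() for t in b.trees_]
    np.testing.assert_array_equal(a.predict(matrix.X), b.predict(matrix.X))


def test_training_loss_nonincreasing_without_sampling(default_corpus):
    matrix = build_design_matrix(default_corpus)
    est = MonotoneGradientBoostingRegressor(
        n_estimators=60, subsample=1.0, colsample_bytree=1.0,
        monotone_constraints=matrix.schema.monotone).fit(matrix.X, matrix.y)
    path = est.train_score_path_
    assert np.all(np.diff(path) <= 1e-12)


def test_zero_tree_model_predicts_base_score(default_corpus):
    matrix = build_design_matrix(default_corpus)
    est = MonotoneGradientBoostingRegressor()
    est.base_score_ = -3.0
    est.trees_ = []
    est.monotone_ = matrix.schema.monotone
    est.n_features_in_ = matrix.schema.n_columns
    np.testing.assert_allclose(est.predict(matrix.X), -3.0)


def test_predict_known_stump_hand_traceable():
    stump = TreeNode(is_leaf=False, feature=1, threshold=0.5,
                     left=TreeNode(is_leaf=True, weight=-1.0),
                     right=TreeNode(is_leaf=True, weight=2.0))
    X = np.array([[9.0, 0.0], [9.0, 1.0], [9.0, 0.49]])
    np.testing.assert_allclose(stump.predict(X), [-1.0, 2.0, -1.0])


def test_predict_schema_mismatch_names_column(default_corpus):
    matrix = build_design_matrix(default_corpus)
    model = fit_booster(matrix, BoostParams(n_estimators=2))
    import dataclasses
    from soluboost.features import DesignMatrix, FeatureSchema, ColumnSpec
    bad_cols = list(matrix.schema.columns)
    bad_cols[0] = dataclasses.replace(bad_cols[0], name="solute=imposter")
    bad = DesignMatrix(matrix.X, matrix.y, FeatureSchema(bad_cols), matrix.row_keys)
    with pytest.raises(ValueError, match="imposter"):
        predict_booster(model, bad)


def test_model_persistence_roundtrip(tmp_path, default_corpus):
    matrix = build_design_matrix(default_corpus)
    model = fit_booster(matrix, BoostParams(n_estimators=8))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = BoostedModel.load(path)
    np.testing.assert_array_equal(loaded.predict(matrix), model.predict(matrix))
    assert loaded.base_score == model.base_score


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        BoostParams(n_estimators=0)
    with pytest.raises(ValueError):
        BoostParams(learning_rate=0.0)
    with pytest.raises(ValueError):
        BoostParams(subsample=1.5)
    with pytest.raises(ValueError):
        BoostParams(gamma=-1.0)
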