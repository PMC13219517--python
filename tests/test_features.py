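import numpy as np
import pytest

from soluboost.data_model import Corpus, SolubilityRecord
from soluboost.features import (
    ColumnSpec,
    FeatureSchema,
    SolubilityFeaturizer,
    build_design_matrix,
    delta_cp,
    encode_categoricals,
    fit_apply_scaler,
)
from soluboost.synthetic import GeneratorConfig, generate_corpus


@pytest.mark.parametrize(
    "solute, T, expected",
    [
        ("butyl paraben", 340.5, 77.2),      # at Tm the linear term vanishes
        ("fenofibrate", 302.05, 98.34),      # 124.3 + 0.5192 * (-50)
        ("risperidone", 442.4, 158.1),
    ],
)
def test_delta_cp_values(solutes, solute, T, expected):
    assert delta_cp(solutes[solute], T) == pytest.approx(expected, abs=1e-10)


def test_delta_cp_rejects_nonpositive_temperature(solutes):
    with pytest.raises(ValueError):
        delta_cp(solutes["butyl paraben"], 0.0)


def _four_solute_corpus(solutes, solvents):
    records = []
    for solute in ("butyl paraben", "fenoxycarb", "fenofibrate", "risperidone"):
        for solvent in ("methanol", "acetone"):
            for T in (283.0, 298.0, 313.0):
                records.append(SolubilityRecord(solute, solvent, T, 0.1))
    return Corpus(records, solutes, solvents)


def test_encoding_shape_and_activation(solutes, solvents):
    corpus = _four_solute_corpus(solutes, solvents)
    M, specs = encode_categoricals(corpus)
    assert len(specs) == 4 + 9  # record solutes + descriptor-table solvents
    assert M.shape == (len(corpus), 13)
    assert np.all(M.sum(axis=1) == 2)  # one solute + one solvent indicator per row
    assert all(s.kind == "indicator" and s.monotone == 0 for s in specs)


def test_unseen_solute_encodes_to_all_zero_block(solutes, solvents):
    train = _four_solute_corpus(solutes, solvents)
    feat = SolubilityFeaturizer().fit(train)
    probe = Corpus([SolubilityRecord("butamben", "methanol", 298.0, 0.1)],
                   solutes, solvents)
    matrix = feat.transform(probe)
    solute_cols = [j for j, n in enumerate(matrix.schema.names) if n.startswith("solute=")]
    solvent_cols = [j for j, n in enumerate(matrix.schema.names) if n.startswith("solvent=")]
    assert np.all(matrix.X[0, solute_cols] == 0)
    assert matrix.X[0, solvent_cols].sum() == 1


def test_column_order_invariant_under_shuffle(solutes, solvents, rng):
    corpus = _four_solute_corpus(solutes, solvents)
    shuffled = Corpus(list(rng.permutation(np.array(corpus.records, dtype=object))),
                      solutes, solvents)
    _, specs_a = encode_categoricals(corpus)
    _, specs_b = encode_categoricals(shuffled)
    assert [s.name for s in specs_a] == [s.name for s in specs_b]


def test_scaler_uses_population_spread_of_fit_rows():
    schema = FeatureSchema([ColumnSpec("T", "continuous", +1), ColumnSpec("c", "continuous")])
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    Xs, fitted = fit_apply_scaler(X, schema, [0, 1, 2])
    expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
    np.testing.assert_allclose(Xs[:, 0], expected, atol=1e-12)
    np.testing.assert_allclose(Xs[:, 1], 0.0)  # constant column guard
    assert fitted.columns[0].scale == pytest.approx(np.sqrt(2.0 / 3.0))
    assert abs(Xs[:, 0].mean()) < 1e-12  # centering identity on fit rows


def test_scaler_statistics_come_from_fit_rows_only():
    schema = FeatureSchema([ColumnSpec("T", "continuous", +1)])
    X = np.array([[0.0], [1.0], [100.0]])
    Xs, fitted = fit_apply_scaler(X, schema, [0, 1])
    assert fitted.columns[0].mean == 0.5
    assert Xs[2, 0] == pytest.approx((100.0 - 0.5) / 0.5)


def test_standardization_preserves_ordering(rng):
    # hence a monotone constraint on scaled T is one on raw T
    v = rng.normal(size=50)
    schema = FeatureSchema([ColumnSpec("T", "continuous", +1)])
    Xs, _ = fit_apply_scaler(v[:, None], schema, np.arange(50))
    assert np.array_equal(np.argsort(v), np.argsort(Xs[:, 0]))


def test_design_matrix_column_count_and_target(solutes, solvents):
    corpus = _four_solute_corpus(solutes, solvents)
    matrix = build_design_matrix(corpus)
    assert matrix.schema.n_columns == 13 + 8
    assert matrix.schema.names[-8:] == list(
        ("T", "dHfus", "Tm", "q", "r", "hansen", "dielectric", "bp"))
    np.testing.assert_allclose(matrix.y, np.log(0.1))
    assert np.all(matrix.y <= 0)


def test_optional_delta_cp_column_matches_direct_recomputation(solutes, solvents):
    corpus = _four_solute_corpus(solutes, solvents)
    matrix = build_design_matrix(corpus, include_delta_cp=True)
    assert matrix.schema.n_columns == 13 + 9
    j = matrix.schema.names.index("dCp")
    col = matrix.schema.columns[j]
    raw = matrix.X[:, j] * col.scale + col.mean  # invert standardization
    expected = [delta_cp(corpus.solute_of(r), r.temperature) for r in corpus.records]
    np.testing.assert_allclose(raw, expected, atol=1e-9)


def test_rows_differing_only_in_T(solutes, solvents):
    from soluboost.features import _raw_matrix
    recs = [SolubilityRecord("butyl paraben", "methanol", T, 0.1) for T in (290.0, 310.0)]
    corpus = Corpus(recs, solutes, solvents)
    X = _raw_matrix(corpus, ["butyl paraben"], sorted(solvents), include_delta_cp=False)
    diff_cols = np.nonzero(X[0] != X[1])[0]
    assert list(diff_cols) == [1 + 9 + 0]  # only the T column


def test_monotone_flag_exactly_on_temperature(default_corpus):
    schema = build_design_matrix(default_corpus).schema
    assert [n for n, m in zip(schema.names, schema.monotone) if m == 1] == ["T"]
    with pytest.raises(ValueError):
        FeatureSchema([ColumnSpec("a", "continuous")])  # no flagged column


def test_schema_roundtrip_and_rebuild_bit_for_bit(tmp_path, default_corpus):
    matrix = build_design_matrix(default_corpus)
    path = tmp_path / "schema.json"
    matrix.schema.save(path)
    loaded = FeatureSchema.load(path)
    assert loaded.to_dict() == matrix.schema.to_dict()
    assert loaded.digest() == matrix.schema.digest()
    rebuilt = build_design_matrix(default_corpus, loaded)
    assert np.array_equal(rebuilt.X, matrix.X) and np.array_equal(rebuilt.y, matrix.y)
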