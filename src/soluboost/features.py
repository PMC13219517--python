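"""Corpus → design matrix: the fixed thermodynamic feature set.

Feature columns, in order:

* one 0/1 indicator per training-set solute and per solvent (lexicographic
  within each block; a name unseen when the schema was fitted maps to an
  all-zero block, which is what makes external-compound prediction possible —
  the signal then flows entirely through the numeric descriptors);
* continuous block: T, ΔHfus, Tm, q, r, Hansen parameter, solvent dielectric
  constant and solvent boiling point.  The two heat-capacity parameters
  enter as static solute descriptors; temperature is deliberately the only
  temperature-varying column, so the +1 monotone constraint on it makes the
  model's entire temperature response nondecreasing — the guarantee the
  constraint exists for.  An explicit ΔCp(T) = q + r·(T − Tm) column can be
  added (``include_delta_cp=True``) at the cost of that global guarantee,
  since the booster's response to the unconstrained ΔCp channel is free.

Continuous columns are standardized with statistics from the fit rows
(population spread; a constant column maps to zeros).  Indicators are left
untouched.  The target is ln x, the natural log of mole-fraction solubility.
Exactly one column — raw temperature — carries the +1 monotone flag handed
to the booster; standardization with positive spread preserves ordering, so
the constraint on scaled T is equivalent to one on raw T.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data_model import Corpus, DescriptorLookupError, SoluteDescriptors, normalize_name

__all__ = [
    "delta_cp",
    "ColumnSpec",
    "FeatureSchema",
    "DesignMatrix",
    "SolubilityFeaturizer",
    "encode_categoricals",
    "fit_apply_scaler",
    "build_design_matrix",
]

CONTINUOUS_NAMES = ("T", "dHfus", "Tm", "q", "r", "hansen", "dielectric", "bp")


def delta_cp(solute: SoluteDescriptors, T: float):
    """ΔCp(T) = q + r·(T − Tm), the liquid−solid heat-capacity difference.

    Linear in temperature; at T = Tm it reduces to q.  Units J/(K·mol).
    """
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive")
    return solute.q + solute.r * (np.asarray(T, dtype=float) - solute.Tm)


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "indicator" | "continuous"
    monotone: int = 0  # +1 on the temperature column only
    mean: float | None = None  # scaler statistics, continuous columns only
    scale: float | None = None

    def __post_init__(self):
        if self.kind not in ("indicator", "continuous"):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == "indicator" and (self.mean is not None or self.monotone != 0):
            raise ValueError("indicator columns carry no scaler statistics or monotone flag")


@dataclass
class FeatureSchema:
    """Ordered column specification with scaler statistics and monotone mask."""

    columns: list[ColumnSpec]

    def __post_init__(self):
        flagged = [c.name for c in self.columns if c.monotone == +1]
        if len(flagged) != 1 or flagged != ["T"]:
            raise ValueError("exactly the temperature column must carry the +1 monotone flag")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def monotone(self) -> np.ndarray:
        return np.array([c.monotone for c in self.columns], dtype=int)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def solute_names(self) -> list[str]:
        return [c.name.split("=", 1)[1] for c in self.columns if c.name.startswith("solute=")]

    def solvent_names(self) -> list[str]:
        return [c.name.split("=", 1)[1] for c in self.columns if c.name.startswith("solvent=")]

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "columns": [
                {"name": c.name, "kind": c.kind, "monotone": c.monotone,
                 "mean": c.mean, "scale": c.scale}
                for c in self.columns
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureSchema":
        return cls([ColumnSpec(**c) for c in payload["columns"]])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "FeatureSchema":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        """Short content hash used to pair a persisted model with its schema."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class DesignMatrix:
    """Numeric feature matrix with target ln x and row keys."""

    X: np.ndarray
    y: np.ndarray  # ln x, ≤ 0
    schema: FeatureSchema
    row_keys: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("matrix and target row counts differ")
        if self.X.shape[1] != self.schema.n_columns:
            raise ValueError("matrix column count does not match schema")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("design matrix contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Back-transformed mole fractions exp(y)."""
        return np.exp(self.y)


def encode_categoricals(corpus: Corpus) -> tuple[np.ndarray, list[ColumnSpec]]:
    """One-hot indicator columns for record solutes and corpus solvents.

    The solute block covers the solute names appearing in the records (the
    training set); the solvent block covers every solvent in the descriptor
    table.  Both blocks are lexicographic in normalized name, so the column
    order is invariant under record shuffling.  No reference level is dropped:
    the all-zero pattern is reserved for names unseen at schema-fit time.
    """
    solute_names = sorted({normalize_name(r.solute) for r in corpus.records})
    solvent_names = sorted(corpus.solvents)
    specs = [ColumnSpec(f"solute={n}", "indicator") for n in solute_names]
    specs += [ColumnSpec(f"solvent={n}", "indicator") for n in solvent_names]
    M = _indicator_matrix(corpus, solute_names, solvent_names)
    return M, specs


def _indicator_matrix(corpus: Corpus, solute_names: Sequence[str],
                      solvent_names: Sequence[str]) -> np.ndarray:
    n = len(corpus.records)
    M = np.zeros((n, len(solute_names) + len(solvent_names)))
    sol_idx = {name: j for j, name in enumerate(solute_names)}
    solv_idx = {name: len(solute_names) + j for j, name in enumerate(solvent_names)}
    for i, rec in enumerate(corpus.records):
        j = sol_idx.get(normalize_name(rec.solute))
        if j is not None:  # unseen solute → all-zero block
            M[i, j] = 1.0
        j = solv_idx.get(normalize_name(rec.solvent))
        if j is not None:
            M[i, j] = 1.0
    return M


def fit_apply_scaler(X: np.ndarray, schema: FeatureSchema,
                     fit_rows: np.ndarray | Sequence[int]) -> tuple[np.ndarray, FeatureSchema]:
    """Standardize continuous columns with statistics from ``fit_rows`` only.

    Population spread; a constant column is mapped to zeros.  Indicator
    columns pass through.  Returns the scaled matrix and a schema updated
    with the fitted statistics.
    """
    fit_rows = np.asarray(fit_rows, dtype=int)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    Xs = X.astype(float).copy()
    new_cols: list[ColumnSpec] = []
    for j, col in enumerate(schema.columns):
        if col.kind != "continuous":
            new_cols.append(col)
            continue
        mean = float(np.mean(X[fit_rows, j]))
        scale = float(np.std(X[fit_rows, j]))  # population formula
        Xs[:, j] = 0.0 if scale == 0.0 else (X[:, j] - mean) / scale
        new_cols.append(ColumnSpec(col.name, col.kind, col.monotone, mean, scale))
    return Xs, FeatureSchema(new_cols)


def _apply_scaler(X: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    Xs = X.astype(float).copy()
    for j, col in enumerate(schema.columns):
        if col.kind != "continuous":
            continue
        if col.mean is None or col.scale is None:
            raise ValueError(f"schema column {col.name!r} has no fitted scaler statistics")
        Xs[:, j] = 0.0 if col.scale == 0.0 else (X[:, j] - col.mean) / col.scale
    return Xs


def _raw_matrix(corpus: Corpus, solute_names: Sequence[str], solvent_names: Sequence[str],
                include_delta_cp: bool) -> np.ndarray:
    ind = _indicator_matrix(corpus, solute_names, solvent_names)
    cont = np.empty((len(corpus.records), len(CONTINUOUS_NAMES) + int(include_delta_cp)))
    for i, rec in enumerate(corpus.records):
        sol = corpus.solutes.get(normalize_name(rec.solute))
        solv = corpus.solvents.get(normalize_name(rec.solvent))
        if sol is None:
            raise DescriptorLookupError(f"no solute descriptors for {rec.solute!r}")
        if solv is None:
            raise DescriptorLookupError(f"no solvent descriptors for {rec.solvent!r}")
        T = rec.temperature
        row = [T, sol.dHfus, sol.Tm, sol.q, sol.r, sol.hansen, solv.dielectric, solv.bp]
        if include_delta_cp:
            row.append(float(delta_cp(sol, T)))
        cont[i] = row
    return np.hstack([ind, cont])


class SolubilityFeaturizer:
    """Transformer from a solubility :class:`Corpus` to a :class:`DesignMatrix`.

    sklearn-style: ``fit`` learns the indicator vocabulary and scaler
    statistics from a training corpus, ``transform`` applies them to any
    corpus (unseen solutes fall back to all-zero indicators).  The fitted
    schema is exposed as ``schema_``.
    """

    def __init__(self, include_delta_cp: bool = False):
        self.include_delta_cp = include_delta_cp

    def fit(self, corpus: Corpus) -> "SolubilityFeaturizer":
        solute_names = sorted({normalize_name(r.solute) for r in corpus.records})
        solvent_names = sorted(corpus.solvents)
        names = CONTINUOUS_NAMES + (("dCp",) if self.include_delta_cp else ())
        specs = [ColumnSpec(f"solute={n}", "indicator") for n in solute_names]
        specs += [ColumnSpec(f"solvent={n}", "indicator") for n in solvent_names]
        specs += [ColumnSpec(n, "continuous", +1 if n == "T" else 0) for n in names]
        X = _raw_matrix(corpus, solute_names, solvent_names, self.include_delta_cp)
        _, self.schema_ = fit_apply_scaler(X, FeatureSchema(specs), np.arange(X.shape[0]))
        return self

    def transform(self, corpus: Corpus) -> DesignMatrix:
        schema = getattr(self, "schema_", None)
        if schema is None:
            raise RuntimeError("featurizer is not fitted")
        X = _raw_matrix(corpus, schema.solute_names(), schema.solvent_names(),
                        "dCp" in schema.names)
        Xs = _apply_scaler(X, schema)
        y = np.log([r.x for r in corpus.records])
        return DesignMatrix(Xs, y, schema, [r.key for r in corpus.records])

    def fit_transform(self, corpus: Corpus) -> DesignMatrix:
        return self.fit(corpus).transform(corpus)


def build_design_matrix(corpus: Corpus, schema: FeatureSchema | None = None,
                        include_delta_cp: bool = False) -> DesignMatrix:
    """Build the design matrix for a corpus.

    Without a schema this is the training path (vocabulary and scaler fitted
    on ``corpus``); with one, the stored schema is reused verbatim — the
    prediction path — and ``include_delta_cp`` is taken from the schema.
    """
    if schema is None:
        return SolubilityFeaturizer(include_delta_cp).fit_transform(corpus)
    f = SolubilityFeaturizer()
    f.schema_ = schema
    return f.transform(corpus)
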