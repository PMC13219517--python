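"""Evaluation against an externally supplied experimental dataset.

The experimental corpus this model family was developed on (224 records for
butyl paraben, fenoxycarb, fenofibrate and risperidone plus 50 external
butamben records) is distributed only as journal supplementary material with
no machine-readable accession, so it cannot be packaged here.  If a copy is
available, place it as ``reference_data/records.csv`` (standard records
format, ``solute,solvent,T_K,x``) next to your working directory, or pass an
explicit path; :func:`evaluate_reference_dataset` then reruns the full
protocol — stratified 80/20 split, monotone booster at the published
hyperparameters, external butamben hold-out — and reports the same summary
statistics the synthetic pipeline computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .booster import PUBLISHED_PARAMS, BoostParams, fit_booster
from .data_model import Corpus, assemble_corpus, normalize_name
from .features import build_design_matrix
from .metrics import mapd, per_system_report, r_squared, rmsle
from .model_selection import leave_one_group_out, random_holdout

__all__ = ["DEFAULT_REFERENCE_PATH", "ReferenceEvaluation", "evaluate_reference_dataset",
           "evaluate_study"]

DEFAULT_REFERENCE_PATH = Path("reference_data") / "records.csv"
EXTERNAL_SOLUTE = "butamben"


@dataclass
class ReferenceEvaluation:
    """Summary statistics of a full run on an experimental corpus."""

    n_records_main: int
    n_records_external: int
    heldout_ln_rmse: float
    overall_rmsle_paper: float
    overall_rmsle_conventional: float
    overall_mapd_pct: float
    train_r2: float
    test_r2: float
    external_rmsle_paper: float
    external_rmsle_by_solvent: dict[str, float]
    external_mapd_pct: float


def evaluate_reference_dataset(records_path=DEFAULT_REFERENCE_PATH,
                               params: BoostParams = PUBLISHED_PARAMS,
                               seed: int = 0,
                               external_solute: str = EXTERNAL_SOLUTE) -> ReferenceEvaluation:
    """Run the full modelling protocol on an experimental records file.

    Raises :class:`FileNotFoundError` when the file is absent.
    """
    records_path = Path(records_path)
    if not records_path.exists():
        raise FileNotFoundError(
            f"reference dataset not found at {records_path}; supply the experimental "
            f"records file to run this evaluation")
    corpus = assemble_corpus(records_path)
    return evaluate_study(corpus, params, seed, external_solute)


def evaluate_study(corpus: Corpus, params: BoostParams = PUBLISHED_PARAMS, seed: int = 0,
                   external_solute: str = EXTERNAL_SOLUTE) -> ReferenceEvaluation:
    """Full protocol on any corpus: 80/20 in-distribution fit of the main
    solutes plus external leave-one-solute-out prediction of ``external_solute``."""
    held = normalize_name(external_solute)

    plan_ext = leave_one_group_out(corpus, "solute", held)
    main_corpus, ext_corpus = plan_ext.apply(corpus)

    # in-distribution protocol on the four main solutes
    plan = random_holdout(main_corpus, 0.8, seed)
    train_c, test_c = plan.apply(main_corpus)
    mtr = build_design_matrix(train_c)
    model = fit_booster(mtr, params)
    mte = build_design_matrix(test_c, mtr.schema)
    pred_tr, pred_te = model.predict(mtr), model.predict(mte)

    x_all = np.concatenate([mtr.x, mte.x])
    xc_all = np.concatenate([np.exp(pred_tr), np.exp(pred_te)])
    frame = _frame(main_corpus, plan, pred_tr, pred_te)
    report = per_system_report(frame)

    # external compound: retrain on every main record, predict the held solute
    m_all = build_design_matrix(main_corpus)
    model_ext = fit_booster(m_all, params)
    m_ext = build_design_matrix(ext_corpus, m_all.schema)
    pred_ext = model_ext.predict(m_ext)
    ext_frame = _simple_frame(ext_corpus, pred_ext)
    ext_report = per_system_report(ext_frame)

    return ReferenceEvaluation(
        n_records_main=len(main_corpus),
        n_records_external=len(ext_corpus),
        heldout_ln_rmse=float(np.sqrt(np.mean((pred_te - mte.y) ** 2))),
        overall_rmsle_paper=float(report.grand_average["RMSLE_paper"]),
        overall_rmsle_conventional=float(report.grand_average["RMSLE_conventional"]),
        overall_mapd_pct=mapd(x_all, xc_all),
        train_r2=r_squared(mtr.y, pred_tr),
        test_r2=r_squared(mte.y, pred_te),
        external_rmsle_paper=float(ext_report.solute_averages["RMSLE_paper"].iloc[0]),
        external_rmsle_by_solvent={
            row.solvent: row.RMSLE_paper for row in ext_report.systems.itertuples()},
        external_mapd_pct=mapd(m_ext.x, np.exp(pred_ext)),
    )


def _frame(corpus: Corpus, plan, pred_train, pred_test):
    import pandas as pd
    train_c, test_c = plan.apply(corpus)
    rows = []
    for c, preds in ((train_c, pred_train), (test_c, pred_test)):
        for rec, p in zip(c.records, preds):
            rows.append({"solute": normalize_name(rec.solute),
                         "solvent": normalize_name(rec.solvent),
                         "T_K": rec.temperature, "x_exp": rec.x, "x_calc": float(np.exp(p))})
    return pd.DataFrame(rows)


def _simple_frame(corpus: Corpus, pred):
    import pandas as pd
    return pd.DataFrame({
        "solute": [normalize_name(r.solute) for r in corpus.records],
        "solvent": [normalize_name(r.solvent) for r in corpus.records],
        "T_K": [r.temperature for r in corpus.records],
        "x_exp": [r.x for r in corpus.records],
        "x_calc": np.exp(pred),
    })
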