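"""Evaluation statistics for solubility models.

Two RMSLE variants are provided because the literature this package follows
uses a non-standard normalisation:

* ``"paper"`` (default):  RMSLE = sqrt(Σ (ln x_exp − ln x_calc)²) / N —
  the whole sum is rooted first and then divided by N;
* ``"conventional"``:     RMSLE = sqrt(Σ (ln x_exp − ln x_calc)² / N).

The two differ by exactly √N.  MAPD is computed on the mole-fraction
(linear) scale so it is directly comparable with the relative scatter of
experimental solubility measurements; R² is computed on ln x, matching how
predicted-vs-experimental solubilities are usually plotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "rmsle",
    "rmsle_from_log",
    "mapd",
    "r_squared",
    "SystemReport",
    "per_system_report",
]


def _validate_pair(x_exp, x_calc):
    x_exp = np.asarray(x_exp, dtype=float)
    x_calc = np.asarray(x_calc, dtype=float)
    if x_exp.shape != x_calc.shape or x_exp.ndim != 1:
        raise ValueError("x_exp and x_calc must be 1-d vectors of equal length")
    if x_exp.size == 0:
        raise ValueError("empty evaluation pair")
    if np.any(x_exp <= 0) or np.any(x_calc <= 0):
        raise ValueError("mole fractions must be strictly positive")
    return x_exp, x_calc


def rmsle(x_exp, x_calc, variant: str = "paper") -> float:
    """Root mean squared logarithmic error between mole-fraction vectors."""
    x_exp, x_calc = _validate_pair(x_exp, x_calc)
    return rmsle_from_log(np.log(x_exp), np.log(x_calc), variant)


def rmsle_from_log(ln_exp, ln_calc, variant: str = "paper") -> float:
    """RMSLE from already-logged values (the booster's native scale)."""
    ln_exp = np.asarray(ln_exp, dtype=float)
    ln_calc = np.asarray(ln_calc, dtype=float)
    sq = (ln_exp - ln_calc) ** 2
    n = sq.size
    if variant == "paper":
        return float(np.sqrt(sq.sum()) / n)
    if variant == "conventional":
        return float(np.sqrt(sq.sum() / n))
    raise ValueError(f"unknown RMSLE variant {variant!r}")


def mapd(x_exp, x_calc) -> float:
    """Mean absolute percentage deviation, in percent, on the linear scale."""
    x_exp, x_calc = _validate_pair(x_exp, x_calc)
    return float(100.0 * np.mean(np.abs(x_calc - x_exp) / x_exp))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (use on ln x)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 paired observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


REPORT_COLUMNS = ["solute", "solvent", "RMSLE_paper", "RMSLE_conventional",
                  "MAPD_pct", "N", "T_min", "T_max"]


@dataclass
class SystemReport:
    """Per-(solute, solvent) evaluation table with solute and grand averages.

    ``systems`` has one row per pair, ordered lexicographically by solute
    then solvent.  ``solute_averages`` holds the arithmetic mean of each
    solute's system rows; ``grand_average`` is the mean over solutes of the
    solute averages (so every compound counts equally regardless of how
    many solvents it was measured in).
    """

    systems: pd.DataFrame
    solute_averages: pd.DataFrame
    grand_average: dict

    def write(self, path, header_comments=()) -> None:
        lines = [f"# {c}" for c in header_comments]
        avg = self.solute_averages.assign(solvent="<average>")
        grand = pd.DataFrame([{**self.grand_average, "solute": "<all solutes>",
                               "solvent": "<average>"}])
        body = pd.concat([self.systems, avg, grand], ignore_index=True)[REPORT_COLUMNS]
        lines.append(body.to_csv(index=False).rstrip("\n"))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def per_system_report(frame: pd.DataFrame) -> SystemReport:
    """Grouped evaluation of predictions.

    ``frame`` needs columns solute, solvent, T_K, x_exp, x_calc (mole
    fractions).  Rows are grouped by (solute, solvent); both RMSLE variants
    and MAPD are evaluated per group, then averaged per solute and grand-
    averaged over solutes.
    """
    required = {"solute", "solvent", "T_K", "x_exp", "x_calc"}
    missing = required.difference(frame.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    rows = []
    for (solute, solvent), grp in frame.groupby(["solute", "solvent"], sort=True):
        rows.append({
            "solute": solute, "solvent": solvent,
            "RMSLE_paper": rmsle(grp["x_exp"], grp["x_calc"], "paper"),
            "RMSLE_conventional": rmsle(grp["x_exp"], grp["x_calc"], "conventional"),
            "MAPD_pct": mapd(grp["x_exp"], grp["x_calc"]),
            "N": len(grp), "T_min": grp["T_K"].min(), "T_max": grp["T_K"].max(),
        })
    systems = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    metric_cols = ["RMSLE_paper", "RMSLE_conventional", "MAPD_pct"]
    solute_avg = (systems.groupby("solute", sort=True)[metric_cols + ["N"]]
                  .agg({**{c: "mean" for c in metric_cols}, "N": "sum"}).reset_index())
    solute_avg["T_min"] = systems.groupby("solute", sort=True)["T_min"].min().values
    solute_avg["T_max"] = systems.groupby("solute", sort=True)["T_max"].max().values
    grand = {c: float(solute_avg[c].mean()) for c in metric_cols} if len(solute_avg) else {
        c: float("nan") for c in metric_cols}
    grand["N"] = int(systems["N"].sum()) if len(systems) else 0
    if len(systems):
        grand["T_min"] = float(systems["T_min"].min())
        grand["T_max"] = float(systems["T_max"].max())
    else:
        grand["T_min"] = grand["T_max"] = float("nan")
    return SystemReport(systems=systems, solute_averages=solute_avg, grand_average=grand)
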