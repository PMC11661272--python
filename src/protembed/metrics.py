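"""Evaluation metrics and ensemble-averaged predictions.

For pKa the interesting quantity is the *shift* from the model-compound
value; the least-squares slope ``m`` is therefore computed on shifts
(predicted − model value regressed on experimental − model value), so a
null model that always returns the model-compound value has m = 0
exactly, and an ideal predictor has m = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricReport", "metrics", "ensemble_average"]


@dataclass
class MetricReport:
    rmse: float
    mape: float | None          # percent; None when any observation is 0
    pearson_r: float | None     # None for constant predictions
    slope: float | None         # shift-regression slope; None without null values
    n: int
    mape_flagged: bool = False
    provenance: dict | None = None

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mape_percent": self.mape,
            "pearson_r": self.pearson_r,
            "slope": self.slope,
            "n": self.n,
        }


def metrics(pred, obs, null_values=None, provenance: dict | None = None) -> MetricReport:
    """RMSE, MAPE (%), Pearson r and (for pKa) the shift slope m.

    ``null_values`` are the per-record model-compound pKa values; when
    given, the slope is fitted on shifts so the null model scores m = 0.
    MAPE is flagged undefined when any observation is zero.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    n = len(pred)
    if n < 2:
        raise ValueError("metrics need at least 2 points")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    mape_flagged = bool(np.any(obs == 0))
    mape = None if mape_flagged else float(np.mean(np.abs(pred - obs) / np.abs(obs)) * 100.0)
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        pearson = None
    else:
        pearson = float(stats.pearsonr(pred, obs).statistic)
    slope = None
    if null_values is not None:
        null_values = np.asarray(null_values, dtype=float)
        x = obs - null_values   # experimental shifts
        y = pred - null_values  # predicted shifts
        if np.ptp(x) == 0:
            slope = None
        else:
            slope = float(np.polyfit(x, y, 1)[0])
    return MetricReport(
        rmse=rmse, mape=mape, pearson_r=pearson, slope=slope, n=n,
        mape_flagged=mape_flagged, provenance=provenance,
    )


def ensemble_average(predictions: pd.DataFrame,
                     group_key: str = "residue",
                     value_key: str = "prediction") -> pd.DataFrame:
    """Average per-conformer predictions for each residue.

    ``predictions`` has one row per (conformer, residue); the result has
    one row per residue with the arithmetic mean prediction and the
    conformer count.  Raises on an empty input group.
    """
    if predictions.empty:
        raise ValueError("empty prediction table")
    grouped = predictions.groupby(group_key)[value_key]
    out = grouped.agg(prediction="mean", n_conformers="count").reset_index()
    if (out["n_conformers"] == 0).any():
        raise ValueError("residue group with no conformers")
    return out
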