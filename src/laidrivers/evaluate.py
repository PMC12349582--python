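"""Goodness-of-fit metrics and their aggregation by vegetation class.

R2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared error) and MAE = mean
absolute error.  Metrics are reported on the test split and on denormalized
LAI, so RMSE and MAE are in m2/m2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["r2", "rmse", "mae", "MetricSummary", "evaluate_predictions",
           "summarize_by_vegetation"]


def _check(observed, predicted, min_n=1):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D with equal length")
    if observed.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {observed.size}")
    return observed, predicted


def r2(observed, predicted) -> float:
    """Coefficient of determination; undefined for constant observations."""
    y, yhat = _check(observed, predicted, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 undefined: observed values are constant")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(observed, predicted) -> float:
    y, yhat = _check(observed, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(observed, predicted) -> float:
    y, yhat = _check(observed, predicted)
    return float(np.mean(np.abs(y - yhat)))


@dataclass
class MetricSummary:
    """Per-grid metric bundle (RMSE/MAE in m2/m2; r2 None if undefined)."""

    grid_id: object
    r2: float | None
    rmse: float
    mae: float
    n: int
    vegetation: str | None = None


def evaluate_predictions(grid_id, observed, predicted, vegetation=None) -> MetricSummary:
    """Metrics for one grid; R2 is omitted (None) when observations are constant."""
    y, yhat = _check(observed, predicted)
    try:
        r2_val = r2(y, yhat)
    except ValueError:
        r2_val = None
    return MetricSummary(grid_id, r2_val, rmse(y, yhat), mae(y, yhat), y.size, vegetation)


def summarize_by_vegetation(summaries) -> pd.DataFrame:
    """Mean and standard deviation of each metric per vegetation class.

    Grids with undefined R2 are excluded from the R2 aggregate but kept for
    RMSE/MAE.  Classes without grids are simply absent from the table.
    """
    rows = [dict(grid_id=s.grid_id, vegetation=s.vegetation, r2=s.r2,
                 rmse=s.rmse, mae=s.mae, n=s.n) for s in summaries]
    if not rows:
        raise ValueError("no metric summaries to aggregate")
    df = pd.DataFrame(rows)
    if df["vegetation"].isna().any():
        raise ValueError("every grid must carry a vegetation label")
    agg = df.groupby("vegetation").agg(
        r2_mean=("r2", "mean"), r2_sd=("r2", lambda s: s.std(ddof=0)),
        rmse_mean=("rmse", "mean"), rmse_sd=("rmse", lambda s: s.std(ddof=0)),
        mae_mean=("mae", "mean"), mae_sd=("mae", lambda s: s.std(ddof=0)),
        n_grids=("grid_id", "count"),
    )
    return agg.reset_index()
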