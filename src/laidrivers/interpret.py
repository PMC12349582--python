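"""Attention-based driver-importance products.

The IMV-LSTM's variable-attention weight Pr(z = soil_moisture) is read as the
per-sample importance of soil moisture; temperature importance is its
complement (one minus).  Downstream products: per-grid dominance maps over a
period (moisture-dominant iff the period-mean importance exceeds 0.5, with
ties going to temperature), seasonal (MAM/JJA/SON/DJF) dominance maps,
per-vegetation importance time series, importance binned against LAI level,
and importance binned against a driver's value with the 0.5 crossing point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .calendar import SEASONS, season_of
from .networks import AttentionRecord

SM_INDEX = 0   # column order of the sample inputs: [soil_moisture, temperature]


@dataclass
class ImportanceSeries:
    """Per-sample soil-moisture importance for one grid, in time order."""

    grid_id: object
    target_dates: pd.DatetimeIndex
    sm_importance: np.ndarray
    vegetation: str | None = None

    def __post_init__(self):
        self.sm_importance = np.asarray(self.sm_importance, dtype=float)
        if len(self.target_dates) != self.sm_importance.size:
            raise ValueError("dates and importance lengths differ")
        if np.any((self.sm_importance < 0) | (self.sm_importance > 1)):
            raise ValueError("importance values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.sm_importance.size

    @property
    def temp_importance(self) -> np.ndarray:
        return 1.0 - self.sm_importance

    @property
    def seasons(self) -> np.ndarray:
        return season_of(self.target_dates.month.to_numpy())


@dataclass
class DominanceMap:
    """Period-mean importance and dominance label per grid."""

    grid_ids: list
    mean_sm_importance: np.ndarray
    labels: list                       # 'moisture' | 'temperature'
    period: str = "all"

    @property
    def area_fractions(self) -> Dict[str, float]:
        n = len(self.labels)
        frac_m = sum(1 for l in self.labels if l == "moisture") / n
        return {"moisture": frac_m, "temperature": 1.0 - frac_m}


def extract_importance(record: AttentionRecord, grid_id, target_dates,
                       vegetation=None) -> ImportanceSeries:
    """Read soil-moisture importance off an attention record's variable weights."""
    w = np.asarray(record.variable_weights, dtype=float)
    if np.any(w < -1e-9) or np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("variable weights are not on the probability simplex")
    return ImportanceSeries(grid_id, pd.DatetimeIndex(target_dates),
                            np.clip(w[:, SM_INDEX], 0.0, 1.0), vegetation)


def dominance_map(series_set: Sequence[ImportanceSeries],
                  months: Iterable[int] | None = None,
                  period: str = "all") -> DominanceMap:
    """Per-grid mean importance over a period, labelled by the 0.5 rule.

    A grid counts as moisture-dominant iff its mean importance is strictly
    greater than 0.5; a mean of exactly 0.5 is temperature-dominant.
    """
    ids, means, labels = [], [], []
    month_set = None if months is None else set(int(m) for m in months)
    for s in series_set:
        vals = s.sm_importance
        if month_set is not None:
            mask = np.isin(s.target_dates.month.to_numpy(), list(month_set))
            vals = vals[mask]
        if vals.size == 0:
            raise ValueError(f"grid {s.grid_id}: no samples in period {period!r}")
        m = float(vals.mean())
        ids.append(s.grid_id)
        means.append(m)
        labels.append("moisture" if m > 0.5 else "temperature")
    return DominanceMap(ids, np.asarray(means), labels, period)


SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


def seasonal_aggregate(series_set: Sequence[ImportanceSeries]) -> Dict[str, DominanceMap]:
    """One dominance map per meteorological season."""
    return {season: dominance_map(series_set, SEASON_MONTHS[season], period=season)
            for season in SEASONS}


def vegetation_timeseries(series_set: Sequence[ImportanceSeries]) -> pd.DataFrame:
    """Class-mean soil-moisture/temperature importance per target date."""
    frames = []
    for s in series_set:
        if s.vegetation is None:
            raise ValueError(f"grid {s.grid_id} lacks a vegetation label")
        frames.append(pd.DataFrame({"date": s.target_dates,
                                    "vegetation": s.vegetation,
                                    "sm_importance": s.sm_importance}))
    df = pd.concat(frames, ignore_index=True)
    out = (df.groupby(["vegetation", "date"], as_index=False)["sm_importance"].mean())
    out["temp_importance"] = 1.0 - out["sm_importance"]
    return out


def importance_vs_lai(series_set: Sequence[ImportanceSeries],
                      lai: Dict[object, np.ndarray], n_bins: int = 20) -> pd.DataFrame:
    """Mean importance in equal-width LAI bins, by season and vegetation class.

    ``lai`` maps grid_id to the denormalized LAI at each series' target dates.
    Empty bins appear with NaN means.
    """
    rows = []
    for s in series_set:
        y = np.asarray(lai[s.grid_id], dtype=float)
        if y.size != len(s):
            raise ValueError(f"grid {s.grid_id}: LAI not aligned with importance")
        rows.append(pd.DataFrame({"vegetation": s.vegetation, "season": s.seasons,
                                  "lai": y, "sm_importance": s.sm_importance}))
    df = pd.concat(rows, ignore_index=True)
    out = []
    for veg, sub in df.groupby("vegetation"):
        lo, hi = sub["lai"].min(), sub["lai"].max()
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(sub["lai"], edges) - 1, 0, n_bins - 1)
        sub = sub.assign(bin=idx)
        for season in SEASONS:
            ssub = sub[sub["season"] == season]
            means = ssub.groupby("bin")["sm_importance"].mean()
            for b in range(n_bins):
                m = means.get(b, np.nan)
                out.append(dict(vegetation=veg, season=season, bin=b,
                                lai_mid=0.5 * (edges[b] + edges[b + 1]),
                                sm_importance=m, temp_importance=1.0 - m))
    return pd.DataFrame(out)


@dataclass
class CrossingResult:
    """Binned importance against a driver plus the equal-importance point."""

    table: pd.DataFrame
    crossing: float | None
    degenerate: bool = False


def importance_vs_driver(series_set: Sequence[ImportanceSeries],
                         driver: Dict[object, np.ndarray], driver_name: str,
                         n_bins: int = 20) -> CrossingResult:
    """Mean importance in equal-width bins of a driver's value.

    The crossing point linearly interpolates the first sign change of
    (temperature importance - 0.5) across bin midpoints; a curve pinned at
    exactly 0.5 from the first bin is flagged degenerate with the crossing at
    the first midpoint; no sign change reports crossing = None.
    """
    vals, imps = [], []
    for s in series_set:
        x = np.asarray(driver[s.grid_id], dtype=float)
        if x.size != len(s):
            raise ValueError(f"grid {s.grid_id}: driver not aligned with importance")
        vals.append(x)
        imps.append(s.sm_importance)
    x = np.concatenate(vals)
    imp = np.concatenate(imps)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    mids, sm_means = [], []
    for b in range(n_bins):
        sel = idx == b
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        sm_means.append(imp[sel].mean() if sel.any() else np.nan)
    mids = np.asarray(mids)
    sm_means = np.asarray(sm_means)
    table = pd.DataFrame({"driver": driver_name, "bin_mid": mids,
                          "sm_importance": sm_means,
                          "temp_importance": 1.0 - sm_means})
    diff = (1.0 - sm_means) - 0.5
    ok = ~np.isnan(diff)
    m, d = mids[ok], diff[ok]
    crossing, degenerate = None, False
    if d.size and d[0] == 0.0:
        crossing, degenerate = float(m[0]), True
    else:
        for k in range(1, d.size):
            if d[k] == 0.0:
                crossing = float(m[k])
                break
            if np.sign(d[k]) != np.sign(d[k - 1]):
                crossing = float(m[k - 1] + (m[k] - m[k - 1]) * (-d[k - 1]) / (d[k] - d[k - 1]))
                break
    return CrossingResult(table, crossing, degenerate)
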