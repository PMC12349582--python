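"""Preprocessing chain: temporal aggregation, validity filtering, fixed-range
min-max normalization, sliding-window sample construction and chronological
splitting.

Normalization uses fixed physical ranges (soil moisture 0-1000 kg/m2,
temperature -50..50 C, LAI 0-10 m2/m2) rather than data-driven extrema, so
normalized values are comparable across grids and runs; out-of-range inputs
raise instead of clipping silently.  Each training sample is a 7-step (56-day)
window of the two forcings with the LAI at the window's final step as target,
and the window advances one composite at a time.  Splits are chronological —
first 70% of samples to training, next 10% to validation, remainder to test —
so evaluation never sees the training period.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import composite_calendar

DEFAULT_WINDOW = 7
DEFAULT_LAI_THRESHOLD = 0.1
SPLIT_NAMES = ("train", "val", "test")


class RangeViolationError(ValueError):
    """A value falls outside its variable's declared physical range."""


class MissingDataError(ValueError):
    """A day or composite window is not fully covered by the input series."""


@dataclass(frozen=True)
class VariableRanges:
    """Fixed normalization ranges per variable, (min, max) in physical units."""

    soil_moisture: tuple = (0.0, 1000.0)
    temperature: tuple = (-50.0, 50.0)
    lai: tuple = (0.0, 10.0)

    def __post_init__(self):
        for name in ("soil_moisture", "temperature", "lai"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"range for {name} must have max > min")

    def of(self, variable: str) -> tuple:
        try:
            return getattr(self, variable)
        except AttributeError:
            raise KeyError(f"unknown variable {variable!r}") from None


def aggregate_daily(values: pd.Series) -> pd.Series:
    """Average sub-daily readings to daily means.

    ``values`` must carry a DatetimeIndex.  Every calendar day between the
    first and last reading must have at least one reading.
    """
    if not isinstance(values.index, pd.DatetimeIndex):
        raise TypeError("aggregate_daily expects a DatetimeIndex")
    if values.empty:
        raise MissingDataError("empty series")
    daily = values.groupby(values.index.normalize()).mean()
    expected = pd.date_range(daily.index[0], daily.index[-1], freq="D")
    missing = expected.difference(daily.index)
    if len(missing):
        raise MissingDataError(f"no readings on {missing[0].date()} "
                               f"({len(missing)} day(s) missing)")
    daily.index.name = "date"
    return daily


def resample_to_composites(daily: pd.Series, start_year: int, n_years: int) -> pd.Series:
    """Average daily values onto the 8-day composite calendar.

    Every composite window of the requested years must be fully covered by
    daily values; the final composite of each year averages its 5-6 days.
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise TypeError("resample_to_composites expects a DatetimeIndex")
    cal = composite_calendar(start_year, n_years)
    out = np.empty(len(cal))
    for k, row in enumerate(cal.itertuples()):
        window = pd.date_range(row.date, periods=row.span_days, freq="D")
        vals = daily.reindex(window)
        if vals.isna().any():
            raise MissingDataError(
                f"composite starting {row.date.date()} not fully covered by daily data")
        out[k] = vals.mean()
    return pd.Series(out, index=pd.DatetimeIndex(cal["date"]), name=daily.name)


def filter_valid_grids(ds: xr.Dataset, threshold: float = DEFAULT_LAI_THRESHOLD) -> xr.DataArray:
    """Boolean keep-mask over grids.

    A grid is kept iff its time-mean LAI is at least ``threshold`` (cells with
    mean strictly below are considered non-vegetated noise) and none of the
    three variables contains missing values.
    """
    if ds.sizes.get("time", 0) == 0:
        raise ValueError("empty time series")
    mean_lai = ds["lai"].mean("time")
    # keep the boundary case (mean exactly at threshold) despite float
    # accumulation error; only strictly-below means are invalid
    keep = mean_lai >= threshold - 1e-9
    for var in ("soil_moisture", "temperature", "lai"):
        keep = keep & ds[var].notnull().all("time")
    keep.name = "valid"
    return keep


def normalize(values: np.ndarray, variable: str,
              ranges: VariableRanges = VariableRanges()) -> np.ndarray:
    """Min-max normalize to [0, 1] using the variable's fixed physical range."""
    values = np.asarray(values, dtype=float)
    lo, hi = ranges.of(variable)
    bad = np.where((values < lo) | (values > hi))
    if bad[0].size:
        idx = tuple(int(b[0]) for b in bad)
        raise RangeViolationError(
            f"{variable} value {values[idx]!r} at index {idx} outside [{lo}, {hi}]")
    return (values - lo) / (hi - lo)


def denormalize(values: np.ndarray, variable: str,
                ranges: VariableRanges = VariableRanges()) -> np.ndarray:
    lo, hi = ranges.of(variable)
    return np.asarray(values, dtype=float) * (hi - lo) + lo


@dataclass
class SampleSet:
    """Windowed samples for one grid (or a pool of grids), in time order.

    inputs: (n, window, 2) normalized [soil_moisture, temperature];
    targets: (n,) normalized LAI at each window's final step.
    """

    grid_id: object
    inputs: np.ndarray
    targets: np.ndarray
    target_dates: pd.DatetimeIndex
    splits: np.ndarray | None = None   # per-sample tag in {train, val, test}
    vegetation: object = None

    def __post_init__(self):
        if self.inputs.ndim != 3 or self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets are inconsistent")
        if len(self.target_dates) != len(self.targets):
            raise ValueError("target_dates length mismatch")
        if not self.target_dates.is_monotonic_increasing:
            raise ValueError("samples must be ordered by target date")

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, split: str) -> "SampleSet":
        if self.splits is None:
            raise ValueError("SampleSet has no split tags; call split_chronological first")
        m = self.splits == split
        return SampleSet(self.grid_id, self.inputs[m], self.targets[m],
                         self.target_dates[m], self.splits[m], self.vegetation)


def build_samples(ds: xr.Dataset, grid_id, window: int = DEFAULT_WINDOW,
                  ranges: VariableRanges = VariableRanges(),
                  vegetation=None) -> SampleSet:
    """Sliding-window samples for one grid of an aligned dataset.

    Produces T - window + 1 samples; sample ``i`` holds normalized soil
    moisture and temperature at steps ``i .. i+window-1`` with the normalized
    LAI at step ``i+window-1`` as target.
    """
    sub = ds.sel(grid=grid_id)
    n_t = sub.sizes["time"]
    if n_t < window:
        raise ValueError(f"series length {n_t} shorter than window {window}")
    sm = normalize(sub["soil_moisture"].values, "soil_moisture", ranges)
    temp = normalize(sub["temperature"].values, "temperature", ranges)
    lai = normalize(sub["lai"].values, "lai", ranges)
    stacked = np.stack([sm, temp], axis=1)               # (T, 2)
    n = n_t - window + 1
    idx = np.arange(window)[None, :] + np.arange(n)[:, None]
    inputs = stacked[idx]                                # (n, window, 2)
    targets = lai[window - 1:]
    dates = pd.DatetimeIndex(sub["time"].values[window - 1:])
    return SampleSet(grid_id, inputs, targets, dates, vegetation=vegetation)


def split_chronological(samples: SampleSet,
                        fractions=(0.7, 0.1, 0.2)) -> SampleSet:
    """Tag samples train/val/test chronologically.

    floor(f_train * n) samples go to training, floor(f_val * n) to validation
    and the remainder to test, preserving time order.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(samples)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} samples leaves an empty subset "
                         f"({n_train}/{n_val}/{n_test})")
    tags = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    return SampleSet(samples.grid_id, samples.inputs, samples.targets,
                     samples.target_dates, tags, samples.vegetation)


def pool_samples(sample_sets: Iterable[SampleSet], split: str | None = None) -> SampleSet:
    """Concatenate per-grid SampleSets (optionally one split only) into a pool.

    The pool is re-sorted by target date so its chronology invariant holds
    across grids.
    """
    parts = [s if split is None else s.subset(split) for s in sample_sets]
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValueError("no samples to pool")
    inputs = np.concatenate([p.inputs for p in parts])
    targets = np.concatenate([p.targets for p in parts])
    dates = pd.DatetimeIndex(np.concatenate([p.target_dates.values for p in parts]))
    splits = (np.concatenate([p.splits for p in parts])
              if all(p.splits is not None for p in parts) else None)
    order = np.argsort(dates.values, kind="stable")
    return SampleSet("pooled", inputs[order], targets[order], dates[order],
                     None if splits is None else splits[order])


def load_igbp_mapping() -> pd.DataFrame:
    """The editable IGBP 17-class -> four-group mapping table."""
    with importlib.resources.files("laidrivers.data").joinpath("igbp_mapping.csv").open() as fh:
        return pd.read_csv(fh)


def aggregate_landcover(codes: Iterable[int],
                        mapping: pd.DataFrame | None = None) -> List[str]:
    """Collapse IGBP class codes to forest / grassland / farmland / non_study."""
    table = (mapping if mapping is not None else load_igbp_mapping())
    lookup: Dict[int, str] = dict(zip(table["igbp_code"].astype(int), table["group"]))
    out = []
    for code in codes:
        code = int(code)
        if code not in lookup:
            raise KeyError(f"unknown IGBP class code {code}")
        out.append(lookup[code])
    return out
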