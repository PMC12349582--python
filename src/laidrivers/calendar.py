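"""8-day composite calendar.

The MODIS LAI convention splits each calendar year into 46 composites whose
start days-of-year are 1, 9, ..., 361.  The first 45 composites span 8 days
each; the final composite absorbs the year's remainder (5 days, 6 in leap
years), so every day of the year belongs to exactly one composite.
"""

from __future__ import annotations

import calendar as _stdcal

import numpy as np
import pandas as pd

COMPOSITES_PER_YEAR = 46
#: start day-of-year of every composite: 1, 9, ..., 361
START_DOYS = np.arange(1, 362, 8)


def composite_calendar(start_year: int, n_years: int) -> pd.DataFrame:
    """Build the composite calendar for ``n_years`` consecutive years.

    Returns a DataFrame with one row per composite and columns
    ``date`` (start date), ``year``, ``doy`` (start day-of-year),
    ``month`` (of the start date) and ``span_days``.
    """
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rows = []
    for year in range(start_year, start_year + n_years):
        days_in_year = 366 if _stdcal.isleap(year) else 365
        for doy in START_DOYS:
            span = 8 if doy < START_DOYS[-1] else days_in_year - START_DOYS[-1] + 1
            date = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(doy) - 1)
            rows.append((date, year, int(doy), date.month, span))
    return pd.DataFrame(rows, columns=["date", "year", "doy", "month", "span_days"])


def composite_fraction_of_year(doy: np.ndarray) -> np.ndarray:
    """Phase of the annual cycle in [0, 1) for composite start days."""
    return (np.asarray(doy, dtype=float) - 1.0) / 365.25


SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SEASONS = ("spring", "summer", "autumn", "winter")


def season_of(months) -> np.ndarray:
    """Map calendar months to meteorological seasons (MAM/JJA/SON/DJF)."""
    months = np.asarray(months)
    return np.array([SEASON_OF_MONTH[int(m)] for m in months.ravel()]).reshape(months.shape)
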