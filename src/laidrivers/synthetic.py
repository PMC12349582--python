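"""Synthetic gridded forcings and LAI with known driver dominance.

The generator emulates the statistical structure of the real inputs — 8-day
composite calendar, physical value ranges (soil moisture 0-1000 kg/m2 over
0-100 cm, air temperature -50..50 C, LAI 0-10 m2/m2), seasonal cycles,
vegetation-type phenology envelopes (unimodal for forest / grassland /
single-season crop, bimodal for double-season rotation crop) and a lagged
dependence of LAI on forcing history — while exposing a ground-truth
dominance parameter ``lambda`` that fixes the fraction of the latent growth
signal attributable to soil moisture.  That known split is what the
importance-recovery tests exploit.

Temperature is a seasonal sinusoid plus white noise; soil moisture is a
mean-reverting AR(1) around a seasonal cycle, so moisture anomalies persist
for weeks the way real root-zone storage does.  LAI is a phenology envelope
(a function of day-of-year per vegetation type) modulated by a saturating
logistic response to the latent growth signal

    G_t = lambda * S~_t + (1 - lambda) * T~_t,

where S~ and T~ are min-max-scaled means of the past ``lag_steps`` composites
of soil moisture and temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import COMPOSITES_PER_YEAR, composite_calendar

VEG_CLASSES = ("forest", "grassland", "crop_single", "crop_double")
ALL_CLASSES = VEG_CLASSES + ("non_vegetated",)

# Physical bounds shared with preprocessing.
SM_RANGE = (0.0, 1000.0)
T_RANGE = (-50.0, 50.0)
LAI_RANGE = (0.0, 10.0)


@dataclass(frozen=True)
class GridSpec:
    """Grid layout and per-cell land-cover labels."""

    n_rows: int
    n_cols: int
    grid_ids: np.ndarray
    landcover: tuple

    def __post_init__(self):
        ids = np.asarray(self.grid_ids)
        if len(np.unique(ids)) != ids.size:
            raise ValueError("grid_ids must be unique")
        if ids.size != self.n_rows * self.n_cols or len(self.landcover) != ids.size:
            raise ValueError("grid_ids/landcover sizes must match n_rows * n_cols")
        for lab in self.landcover:
            if lab not in ALL_CLASSES:
                raise ValueError(f"unknown land-cover label {lab!r}")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def default(cls, n_rows: int = 4, n_cols: int = 4) -> "GridSpec":
        """Deterministic test grid cycling the four vegetation classes, with
        the last cell left non-vegetated to exercise the validity filter."""
        n = n_rows * n_cols
        labels = [VEG_CLASSES[i % len(VEG_CLASSES)] for i in range(n - 1)] + ["non_vegetated"]
        return cls(n_rows, n_cols, np.arange(n), tuple(labels))


def _default_envelopes() -> Dict[str, dict]:
    # For the unimodal classes the annual LAI cycle is not imposed by the
    # calendar: their envelope gain is flat and the seasonality of LAI emerges
    # from the growth signal G (whose drivers have seasonal cycles).  That
    # keeps LAI's dependence genuinely split between the drivers by lambda —
    # a day-of-year-shaped envelope would hand most of the variance to
    # whichever variable best proxies the calendar.  The double-cropping
    # class is the exception: its two Gaussian bumps (winter-wheat and
    # summer-maize cycles separated by a harvest dip) are management-driven
    # and therefore calendar-gated.  ``amplitude`` is the class's typical
    # peak LAI contribution (m2/m2) above ``base``.
    return {
        "forest": dict(amplitude=5.5, base=0.4),
        "grassland": dict(amplitude=2.5, base=0.15),
        "crop_single": dict(amplitude=4.0, base=0.1),
        "crop_double": dict(peak_doy=135.0, width_days=22.0, amplitude=4.5, base=0.1,
                            second_peak_offset=95.0, second_width_days=25.0,
                            second_amplitude=4.0),
        "non_vegetated": dict(amplitude=0.0, base=0.02),
    }


@dataclass
class CouplingParams:
    """Ground-truth coupling between forcings and LAI.

    ``dominance_lambda`` is the weight of soil moisture in the latent growth
    signal (1 = moisture-only, 0 = temperature-only).  ``lag_steps`` is the
    number of 8-day composites of forcing history that LAI integrates; the
    default 3 (24 days) sits inside the 7-step (56-day) model window.
    """

    dominance_lambda: float = 0.5
    lag_steps: int = 3
    noise_sd_T: float = 1.5        # C, per-composite white noise
    noise_sd_SM: float = 15.0      # kg/m2, AR(1) innovation sd
    noise_sd_LAI: float = 0.1      # m2/m2
    t_mean: float = 9.0            # C, regional annual mean
    t_amplitude: float = 13.0      # C, seasonal half-range
    t_peak_doy: float = 205.0      # annual temperature maximum (late July)
    sm_mean: float = 300.0         # kg/m2 over 0-100 cm
    sm_amplitude: float = 50.0     # kg/m2 seasonal half-range (monsoon peak)
    sm_peak_doy: float = 245.0     # monsoon storage maximum (~40 d after T peak)
    sm_ar1: float = 0.9            # 8-day-step persistence of moisture anomalies
    response_steepness: float = 5.0
    envelopes: Dict[str, dict] = field(default_factory=_default_envelopes)

    def __post_init__(self):
        if not 0.0 <= self.dominance_lambda <= 1.0:
            raise ValueError("dominance_lambda must lie in [0, 1]")
        if self.lag_steps < 1:
            raise ValueError("lag_steps must be >= 1")
        for name in ("noise_sd_T", "noise_sd_SM", "noise_sd_LAI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _seasonal(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def generate_forcings(spec: GridSpec, years: int, params: CouplingParams,
                      seed: int, start_year: int = 2000) -> xr.Dataset:
    """Per-grid soil-moisture and temperature series on the composite calendar.

    Cells get small deterministic mean offsets (a northwest-to-southeast
    gradient) so grids differ without extra randomness.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    cal = composite_calendar(start_year, years)
    doy = cal["doy"].to_numpy(dtype=float)
    n_t = len(cal)
    rng = np.random.default_rng(seed)

    rows, cols = np.divmod(np.arange(spec.n_cells), spec.n_cols)
    # gentle spatial gradients: drier/colder toward the first row/col
    grad = (rows / max(spec.n_rows - 1, 1) + cols / max(spec.n_cols - 1, 1)) / 2.0
    t_off = (grad - 0.5) * 3.0       # +-1.5 C across the grid
    sm_off = (grad - 0.5) * 40.0     # +-20 kg/m2 across the grid

    temp = np.empty((spec.n_cells, n_t))
    sm = np.empty((spec.n_cells, n_t))
    seas_t = _seasonal(doy, params.t_peak_doy)
    seas_sm = _seasonal(doy, params.sm_peak_doy)
    for g in range(spec.n_cells):
        temp[g] = (params.t_mean + t_off[g] + params.t_amplitude * seas_t
                   + rng.normal(0.0, params.noise_sd_T, n_t) if params.noise_sd_T > 0
                   else params.t_mean + t_off[g] + params.t_amplitude * seas_t)
        mean_g = params.sm_mean + sm_off[g]
        anom = 0.0
        series = np.empty(n_t)
        innov = rng.normal(0.0, params.noise_sd_SM, n_t) if params.noise_sd_SM > 0 else np.zeros(n_t)
        for t in range(n_t):
            anom = params.sm_ar1 * anom + innov[t]
            series[t] = mean_g + params.sm_amplitude * seas_sm[t] + anom
        sm[g] = series
    temp = np.clip(temp, *T_RANGE)
    sm = np.clip(sm, *SM_RANGE)

    return xr.Dataset(
        {
            "soil_moisture": (("grid", "time"), sm, {"units": "kg m-2", "long_name": "0-100 cm soil moisture"}),
            "temperature": (("grid", "time"), temp, {"units": "degC", "long_name": "air temperature"}),
        },
        coords={
            "grid": ("grid", np.asarray(spec.grid_ids)),
            "time": ("time", cal["date"].to_numpy()),
            "doy": ("time", cal["doy"].to_numpy()),
            "year": ("time", cal["year"].to_numpy()),
        },
        attrs={"calendar": "modis-8day", "composites_per_year": COMPOSITES_PER_YEAR},
    )


def _lagged_mean(x: np.ndarray, lag: int) -> np.ndarray:
    """Trailing mean over the past ``lag`` steps (inclusive of the current)."""
    kernel = np.ones(lag) / lag
    padded = np.concatenate([np.full(lag - 1, x[0]), x])
    return np.convolve(padded, kernel, mode="valid")


def _scale_fixed(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Scale to [0, 1] against fixed anchors shared by all grids.

    Using parameter-level anchors (rather than each grid's own extrema) keeps
    the ground-truth map from forcing history to LAI identical across grids,
    so wetter/drier cells genuinely sit higher/lower on the response curve.
    """
    if hi - lo < 1e-12:
        return np.full_like(x, 0.5)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def _driver_anchors(params: "CouplingParams") -> tuple:
    """(lo, hi) scaling anchors for soil moisture and temperature."""
    anom_sd = (params.noise_sd_SM / np.sqrt(1.0 - params.sm_ar1 ** 2)
               if params.sm_ar1 < 1.0 else params.noise_sd_SM)
    sm_half = params.sm_amplitude + 2.0 * anom_sd
    t_half = params.t_amplitude + 2.0 * params.noise_sd_T
    return ((params.sm_mean - sm_half, params.sm_mean + sm_half),
            (params.t_mean - t_half, params.t_mean + t_half))


def envelope(veg: str, doy: np.ndarray, params: CouplingParams) -> np.ndarray:
    """Multiplicative envelope gain in m2/m2 (excludes the ``base`` floor).

    Flat (= amplitude) for unimodal classes; the bimodal double-cropping
    gain has two intra-annual peaks with a harvest dip between them.
    """
    e = params.envelopes[veg]
    doy = np.asarray(doy, dtype=float)
    if "peak_doy" in e:                      # bimodal (double-cropping) class
        gain = e["amplitude"] * np.exp(
            -0.5 * ((doy - e["peak_doy"]) / e["width_days"]) ** 2)
        second_doy = e["peak_doy"] + e["second_peak_offset"]
        gain = gain + e["second_amplitude"] * np.exp(
            -0.5 * ((doy - second_doy) / e["second_width_days"]) ** 2)
        return gain
    return np.full_like(doy, e["amplitude"])


def generate_lai(forcings: xr.Dataset, spec: GridSpec, params: CouplingParams,
                 seed: int) -> xr.Dataset:
    """LAI per grid from the latent growth signal and phenology envelopes."""
    if forcings.sizes["grid"] != spec.n_cells:
        raise ValueError("forcings grid dimension does not match the GridSpec")
    if not np.array_equal(forcings["grid"].values, np.asarray(spec.grid_ids)):
        raise ValueError("forcings grid ids do not match the GridSpec (calendar misalignment)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    doy = forcings["doy"].values
    lam = params.dominance_lambda
    n_t = forcings.sizes["time"]
    lai = np.empty((spec.n_cells, n_t))
    (sm_lo, sm_hi), (t_lo, t_hi) = _driver_anchors(params)
    for g, veg in enumerate(spec.landcover):
        s_tilde = _scale_fixed(_lagged_mean(forcings["soil_moisture"].values[g],
                                            params.lag_steps), sm_lo, sm_hi)
        t_tilde = _scale_fixed(_lagged_mean(forcings["temperature"].values[g],
                                            params.lag_steps), t_lo, t_hi)
        growth = lam * s_tilde + (1.0 - lam) * t_tilde
        response = 1.0 / (1.0 + np.exp(-params.response_steepness * (growth - 0.5)))
        base = params.envelopes[veg]["base"]
        series = base + envelope(veg, doy, params) * response
        if veg == "non_vegetated":
            series = np.full(n_t, base)
        if params.noise_sd_LAI > 0:
            series = series + rng.normal(0.0, params.noise_sd_LAI, n_t)
        lai[g] = np.clip(series, *LAI_RANGE)
    ds = forcings.copy()
    ds["lai"] = (("grid", "time"), lai, {"units": "m2 m-2", "long_name": "leaf area index"})
    return ds


def simulate_dataset(spec: GridSpec, years: int, params: CouplingParams,
                     seed: int, start_year: int = 2000) -> xr.Dataset:
    """Full simulation: forcings then LAI, sharing one seed stream."""
    forcings = generate_forcings(spec, years, params, seed, start_year=start_year)
    ds = generate_lai(forcings, spec, params, seed)
    ds.attrs["dominance_lambda"] = params.dominance_lambda
    ds.attrs["seed"] = seed
    return ds


def save_dataset(ds: xr.Dataset, path, landcover_path=None, spec: GridSpec | None = None) -> None:
    """Write the gridded series as NetCDF and (optionally) land cover as CSV."""
    ds.to_netcdf(path, engine="scipy")
    if landcover_path is not None:
        if spec is None:
            raise ValueError("spec is required to write the land-cover table")
        pd.DataFrame({"grid_id": np.asarray(spec.grid_ids),
                      "label": list(spec.landcover)}).to_csv(landcover_path, index=False)


def load_dataset(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()
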