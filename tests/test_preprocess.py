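import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from laidrivers import preprocess as pp
from laidrivers.preprocess import (MissingDataError, RangeViolationError,
                                   SampleSet, VariableRanges, aggregate_daily,
                                   aggregate_landcover, build_samples,
                                   denormalize, filter_valid_grids, normalize,
                                   pool_samples, resample_to_composites,
                                   split_chronological)


class TestAggregateDaily:
    def test_constant_readings_average_to_constant(self):
        idx = pd.date_range("2001-03-01", periods=16, freq="3h")
        out = aggregate_daily(pd.Series(12.0, index=idx))
        assert (out == 12.0).all()

    def test_hand_computed_mean(self):
        idx = pd.date_range("2001-03-01", periods=8, freq="3h")
        out = aggregate_daily(pd.Series([0, 3, 6, 9, 12, 15, 18, 21], index=idx, dtype=float))
        assert out.iloc[0] == 10.5

    def test_missing_day_raises(self):
        idx = pd.DatetimeIndex(["2001-03-01", "2001-03-03"])
        with pytest.raises(MissingDataError, match="2001-03-02"):
            aggregate_daily(pd.Series([1.0, 2.0], index=idx))


class TestResample:
    def test_constant_series_idempotent(self):
        daily = pd.Series(3.5, index=pd.date_range("2001-01-01", "2001-12-31"))
        out = resample_to_composites(daily, 2001, 1)
        assert len(out) == 46
        assert np.allclose(out.values, 3.5)

    def test_window_mean_of_one_through_eight(self):
        daily = pd.Series(0.0, index=pd.date_range("2001-01-01", "2001-12-31"))
        daily.iloc[:8] = np.arange(1, 9, dtype=float)
        assert resample_to_composites(daily, 2001, 1).iloc[0] == 4.5

    def test_final_composite_averages_year_remainder(self):
        daily = pd.Series(0.0, index=pd.date_range("2001-01-01", "2001-12-31"))
        daily.loc["2001-12-27":] = [1, 2, 3, 4, 5]       # doy 361..365
        assert resample_to_composites(daily, 2001, 1).iloc[-1] == 3.0

    def test_partial_coverage_raises(self):
        daily = pd.Series(1.0, index=pd.date_range("2001-01-05", "2001-12-31"))
        with pytest.raises(MissingDataError):
            resample_to_composites(daily, 2001, 1)


class TestValidityFilter:
    def test_bare_cell_excluded_boundary_kept(self, small_dataset, small_spec):
        keep = filter_valid_grids(small_dataset)
        labels = dict(zip(np.asarray(small_spec.grid_ids), small_spec.landcover))
        for gid in np.asarray(small_dataset.grid.values):
            if labels[gid] == "non_vegetated":
                assert not bool(keep.sel(grid=gid))
            else:
                assert bool(keep.sel(grid=gid))

    def test_mean_exactly_at_threshold_is_kept(self, small_dataset):
        ds = small_dataset.copy(deep=True)
        ds["lai"].values[:] = 0.1
        assert bool(filter_valid_grids(ds).all())

    def test_grid_with_missing_values_dropped(self, small_dataset):
        ds = small_dataset.copy(deep=True)
        ds["soil_moisture"].values[2, 5] = np.nan
        assert not bool(filter_valid_grids(ds).values[2])


class TestNormalize:
    def test_fixed_range_examples(self):
        assert normalize(np.array([25.0]), "temperature")[0] == pytest.approx(0.75)
        assert normalize(np.array([0.0]), "soil_moisture")[0] == 0.0
        assert normalize(np.array([10.0]), "lai")[0] == 1.0

    def test_out_of_range_names_variable_and_index(self):
        with pytest.raises(RangeViolationError, match=r"temperature.*\(2,\)"):
            normalize(np.array([0.0, 1.0, 99.0]), "temperature")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        for var, (lo, hi) in [("soil_moisture", (0, 1000)),
                              ("temperature", (-50, 50)), ("lai", (0, 10))]:
            x = rng.uniform(lo, hi, size=20)
            assert np.allclose(denormalize(normalize(x, var), var), x, atol=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="max > min"):
            VariableRanges(temperature=(10.0, 10.0))


class TestWindowing:
    def test_sample_count_matches_enumeration(self, small_dataset):
        s = build_samples(small_dataset, 3, window=7)
        T = small_dataset.sizes["time"]
        assert len(s) == T - 7 + 1
        # brute-force window enumeration oracle on the normalized series
        sm = normalize(small_dataset.sel(grid=3).soil_moisture.values, "soil_moisture")
        for i in (0, 17, len(s) - 1):
            assert np.allclose(s.inputs[i, :, 0], sm[i:i + 7])

    def test_window_equals_series_gives_single_sample(self, small_dataset):
        ds = small_dataset.isel(time=slice(0, 7))
        s = build_samples(ds, 0, window=7)
        assert len(s) == 1

    def test_target_is_lai_at_final_step(self, small_dataset):
        s = build_samples(small_dataset, 5, window=7)
        lai = normalize(small_dataset.sel(grid=5).lai.values, "lai")
        assert np.allclose(s.targets, lai[6:])
        assert s.target_dates[0] == pd.Timestamp(small_dataset.time.values[6])

    def test_too_short_series_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="shorter"):
            build_samples(small_dataset.isel(time=slice(0, 5)), 0, window=7)


class TestSplit:
    def _samples(self, n):
        dates = pd.date_range("2000-01-01", periods=n, freq="8D")
        return SampleSet("g", np.zeros((n, 7, 2)), np.zeros(n), dates)

    @pytest.mark.parametrize("n,sizes", [(10, (7, 1, 2)), (1006, (704, 100, 202))])
    def test_floor_rule_sizes(self, n, sizes):
        tagged = split_chronological(self._samples(n))
        counts = tuple((tagged.splits == k).sum() for k in ("train", "val", "test"))
        assert counts == sizes

    def test_chronology_never_leaks(self, small_dataset):
        s = split_chronological(build_samples(small_dataset, 1))
        t = s.subset("train").target_dates
        v = s.subset("val").target_dates
        te = s.subset("test").target_dates
        assert t.max() < v.min() < v.max() < te.min()

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_chronological(self._samples(5))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_chronological(self._samples(100), fractions=(0.5, 0.1, 0.1))


class TestPooling:
    def test_pool_is_chronological_and_complete(self, small_dataset, small_spec):
        sets = [split_chronological(build_samples(small_dataset, g))
                for g in (0, 1, 2)]
        pooled = pool_samples(sets)
        assert len(pooled) == sum(len(s) for s in sets)
        assert pooled.target_dates.is_monotonic_increasing


class TestLandcover:
    @pytest.mark.parametrize("code,expected", [
        (5, "forest"),           # mixed forest
        (4, "forest"),           # deciduous broadleaf
        (14, "farmland"),        # cropland/natural mosaic
        (12, "farmland"),
        (10, "grassland"),
        (13, "non_study"),       # urban
        (16, "non_study"),       # barren
    ])
    def test_igbp_aggregation_rules(self, code, expected):
        assert aggregate_landcover([code]) == [expected]

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError, match="99"):
            aggregate_landcover([99])
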