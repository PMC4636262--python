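"""The four-branch daily degree-day rule and its accumulations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenodd import (
    DDSeries,
    Region,
    accumulate,
    daily_delta_dd,
    fixed_window_dd,
    regional_average,
    t0_scan,
)
from phenodd.degree_days import (
    WHOLE_YEAR,
    read_regional_dd_csv,
    regional_table,
    t0_values,
    write_regional_dd_csv,
)
from phenodd.errors import MissingDataError


def brute_delta_dd(tmax, tmin, t0):
    """Scalar re-statement of the weighted rule, used as oracle."""
    tmean = 0.5 * (tmax + tmin)
    if tmax <= t0:
        return 0.0
    if tmin >= t0:
        return tmean - t0
    if tmean >= t0:
        return 0.5 * (tmax - t0) - 0.25 * (t0 - tmin)
    return 0.25 * (tmax - t0)


class TestDailyDeltaDD:
    @pytest.mark.parametrize(
        "tmax, tmin, t0, expected",
        [
            (4.0, -2.0, 5.5, 0.0),        # cold day, tmax below threshold
            (20.0, 10.0, 5.5, 9.5),       # fully above: tmean - t0
            (15.0, 5.0, 5.5, 4.625),      # warm mean, cool night
            (8.0, 0.0, 5.5, 0.625),       # cool mean, warm afternoon
            (5.5, 5.5, 5.5, 0.0),         # all branches meet at the threshold
        ],
    )
    def test_branch_examples(self, tmax, tmin, t0, expected):
        assert daily_delta_dd(tmax, tmin, t0) == pytest.approx(expected)

    def test_rejects_inverted_extremes(self):
        with pytest.raises(ValueError):
            daily_delta_dd(1.0, 2.0, 5.0)

    def test_bulk_random_properties(self):
        """Non-negativity, oracle agreement and monotonicity on 1e5 draws."""
        rng = np.random.default_rng(7)
        n = 100_000
        tmin = rng.uniform(-30, 25, n)
        tmax = tmin + rng.uniform(0, 25, n)
        t0 = rng.uniform(0, 10, n)
        vals = np.array([daily_delta_dd(a, b, c) for a, b, c in
                         zip(tmax[:200], tmin[:200], t0[:200])])
        oracle = np.array([brute_delta_dd(a, b, c) for a, b, c in
                           zip(tmax[:200], tmin[:200], t0[:200])])
        np.testing.assert_allclose(vals, oracle, atol=1e-12)

        # vectorized evaluation over the full sample
        v = daily_delta_dd(tmax, tmin, np.median(t0))
        assert np.all(v >= 0)
        t0s = np.full(n, 5.0)
        base = daily_delta_dd(tmax, tmin, 5.0)
        assert np.all(daily_delta_dd(tmax, tmin, 5.5) <= base + 1e-12)  # down in t0
        assert np.all(daily_delta_dd(tmax + 0.5, tmin, 5.0) >= base - 1e-12)
        assert np.all(daily_delta_dd(tmax, np.minimum(tmin + 0.5, tmax), 5.0)
                      >= base - 1e-12)

    @given(
        tmin=st.floats(-30, 25),
        spread=st.floats(0, 25),
        t0=st.floats(0, 10),
    )
    @settings(max_examples=300, derandomize=True)
    def test_non_negative_everywhere(self, tmin, spread, t0):
        assert daily_delta_dd(tmin + spread, tmin, t0) >= 0

    @pytest.mark.parametrize("eps", [1e-6, 1e-9])
    def test_continuity_at_branch_boundaries(self, eps):
        t0 = 5.5
        # tmin crossing t0 (branch 2 <-> 3)
        a = daily_delta_dd(12.0, t0 + eps, t0)
        b = daily_delta_dd(12.0, t0 - eps, t0)
        assert a == pytest.approx(b, abs=1e-5)
        # tmean crossing t0 (branch 3 <-> 4): tmean == t0 at tmin = 2*t0 - tmax
        tmax = 9.0
        tmin0 = 2 * t0 - tmax
        a = daily_delta_dd(tmax, tmin0 + eps, t0)
        b = daily_delta_dd(tmax, tmin0 - eps, t0)
        assert a == pytest.approx(b, abs=1e-5)
        # tmax crossing t0 (branch 1 <-> 4)
        a = daily_delta_dd(t0 + eps, -5.0, t0)
        b = daily_delta_dd(t0 - eps, -5.0, t0)
        assert a == pytest.approx(b, abs=1e-5)


class TestAccumulate:
    def test_constant_climate_unit_slope(self, constant_grid):
        """tmax = tmin = 6.5, t0 = 5.5: exactly 1 degree-day per day."""
        series = accumulate(constant_grid, (0, 0), 2003, 5.5)
        np.testing.assert_allclose(series.cumulative, np.arange(1, 366))

    def test_all_cold_days_zero(self, constant_grid):
        series = accumulate(constant_grid, (0, 0), 2003, 10.0)
        assert np.all(series.cumulative == 0)

    def test_leap_year_length(self, constant_grid):
        assert len(accumulate(constant_grid, (0, 0), 2004, 5.5).cumulative) == 366

    def test_matches_running_sum_oracle(self, seasonal_grid):
        cell, year, t0 = (1, 1), 2004, 3.5
        series = accumulate(seasonal_grid, cell, year, t0)
        tmax, tmin = seasonal_grid.cell_year(cell, year)
        running, total = [], 0.0
        for a, b in zip(tmax, tmin):
            total += brute_delta_dd(a, b, t0)
            running.append(total)
        np.testing.assert_allclose(series.cumulative, running, atol=1e-9)

    def test_missing_day_refused(self, constant_grid):
        constant_grid.tmax[40, 0, 0] = np.nan
        constant_grid.tmin[40, 0, 0] = np.nan
        with pytest.raises(MissingDataError):
            accumulate(constant_grid, (0, 0), 2003, 5.5)

    def test_warm_limit_uniform_shift(self, small_spec):
        """With tmin >= t0 all year, +delta raises the annual total by
        delta * days."""
        import pandas as pd
        from phenodd import TemperatureGrid
        dates = pd.date_range("2003-01-01", "2003-12-31", freq="D")
        shape = (len(dates), small_spec.n_lat, small_spec.n_lon)
        grid = TemperatureGrid(small_spec, dates, np.full(shape, 20.0),
                               np.full(shape, 12.0))
        base = accumulate(grid, (0, 0), 2003, 5.5).cumulative[-1]
        shifted = TemperatureGrid(small_spec, dates, grid.tmax + 1.5,
                                  grid.tmin + 1.5)
        total = accumulate(shifted, (0, 0), 2003, 5.5).cumulative[-1]
        assert total - base == pytest.approx(1.5 * 365)


class TestRegionalAverage:
    def test_identical_cells_equal_any_member(self, constant_grid, small_region):
        series = [accumulate(constant_grid, c, 2003, 5.5)
                  for c in small_region.cells]
        table = regional_average(series, small_region)
        np.testing.assert_allclose(table.years[2003], series[0].cumulative)

    def test_mean_of_slopes(self, small_region):
        s1 = DDSeries(cell=(0, 0), year=2003, t0=5.5,
                      cumulative=1.0 * np.arange(1, 366))
        s2 = DDSeries(cell=(1, 0), year=2003, t0=5.5,
                      cumulative=3.0 * np.arange(1, 366))
        table = regional_average([s1, s2], small_region)
        np.testing.assert_allclose(table.years[2003], 2.0 * np.arange(1, 366))

    def test_mean_of_cumulatives_is_cumulative_of_mean(self, seasonal_grid,
                                                       small_region):
        series = [accumulate(seasonal_grid, c, 2003, 5.5)
                  for c in sorted(small_region.cells)]
        table = regional_average(series, small_region)
        daily = np.mean([np.diff(np.concatenate([[0], s.cumulative]))
                         for s in series], axis=0)
        np.testing.assert_allclose(table.years[2003], np.cumsum(daily),
                                   atol=1e-9)

    def test_empty_input_rejected(self, small_region):
        with pytest.raises(ValueError):
            regional_average([], small_region)


class TestFixedWindow:
    def test_jul31_day_count(self):
        series = DDSeries(cell=(0, 0), year=2003, t0=5.5,
                          cumulative=1.0 * np.arange(1, 366))
        assert fixed_window_dd(series, end=(7, 31)) == 212.0

    def test_jul31_leap_year(self):
        series = DDSeries(cell=(0, 0), year=2004, t0=5.5,
                          cumulative=1.0 * np.arange(1, 367))
        assert fixed_window_dd(series, end=(7, 31)) == 213.0

    def test_whole_year(self):
        series = DDSeries(cell=(0, 0), year=2003, t0=5.5,
                          cumulative=1.0 * np.arange(1, 366))
        assert fixed_window_dd(series, end=WHOLE_YEAR) == 365.0

    def test_jan1_is_first_day_contribution(self, seasonal_grid):
        series = accumulate(seasonal_grid, (0, 0), 2003, 0.0)
        assert fixed_window_dd(series, end=(1, 1)) == series.cumulative[0]


class TestT0Scan:
    def test_default_grid_has_21_values(self):
        vals = t0_values()
        assert len(vals) == 21
        assert vals[0] == 0.0 and vals[-1] == 10.0 and vals[1] == 0.5

    def test_step_larger_than_range(self):
        assert t0_values(2.0, 3.0, 5.0) == [2.0]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            t0_values(5.0, 1.0)

    def test_tables_decrease_with_t0(self, seasonal_grid, small_region):
        tables = t0_scan(seasonal_grid, small_region, [2003], 0.0, 10.0, 2.5)
        t0s = sorted(tables)
        for lo, hi in zip(t0s, t0s[1:]):
            assert np.all(tables[hi].years[2003] <= tables[lo].years[2003] + 1e-9)


class TestRegionalDDCSV:
    def test_round_trip(self, tmp_path, seasonal_grid, small_region):
        tables = [regional_table(seasonal_grid, small_region, [2003, 2004], t0)
                  for t0 in (0.0, 5.5)]
        path = tmp_path / "dd.csv"
        write_regional_dd_csv(tables, path)
        back = read_regional_dd_csv(path)
        key = (small_region.name, 5.5)
        np.testing.assert_allclose(back[key].years[2004],
                                   tables[1].years[2004], atol=1e-9)
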