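"""First-crossing model, RMSE calibration, consistency and point test."""

import numpy as np
import pytest

from phenodd import (
    ClimateScenario,
    DDCSearchGrid,
    GridSpec,
    ModelSpec,
    ObserverModel,
    Region,
    accumulate,
    build_ff_dataset,
    calibrate,
    calibrate_region,
    consistency_metrics,
    dedupe_location_year,
    model_ff_date,
    point_test,
    primary_ddc_range,
    regional_table,
    rmse_days,
    select_best_model,
    simulate_sightings_sva,
    simulate_temperature,
)
from phenodd.errors import DataError, NoCommonYearsError
from phenodd.ff_model import RMSECurve
from phenodd.observations import SVA


class TestModelFFDate:
    def test_first_crossing(self):
        cum = np.arange(1.0, 366.0)
        assert model_ff_date(cum, 100) == 100
        assert model_ff_date(cum, 100.5) == 101

    def test_not_reached_is_a_value(self):
        assert model_ff_date(np.arange(1.0, 366.0), 400) is None

    def test_monotone_in_ddc(self):
        rng = np.random.default_rng(3)
        cum = np.cumsum(rng.uniform(0, 3, 365))
        days = [model_ff_date(cum, c) for c in np.linspace(1, cum[-1], 50)]
        assert all(a <= b for a, b in zip(days, days[1:]))


class TestRMSE:
    def test_identical_maps(self):
        assert rmse_days({2003: 120, 2004: 125}, {2003: 120, 2004: 125}) == 0.0

    def test_constant_offset(self):
        model = {y: 100 + y % 7 for y in range(2000, 2010)}
        obs = {y: v + 3 for y, v in model.items()}
        assert rmse_days(model, obs) == pytest.approx(3.0)

    def test_mixed_residuals(self):
        assert rmse_days({1: 103, 2: 96}, {1: 100, 2: 100}) == pytest.approx(
            np.sqrt((9 + 16) / 2))

    def test_skips_uncommon_years(self):
        assert rmse_days({1: 100, 2: 110}, {1: 100, 3: 50}) == 0.0

    def test_no_common_years(self):
        with pytest.raises(NoCommonYearsError):
            rmse_days({1: 100}, {2: 100})


def _noiseless_world(dd_c=160.0, t0=5.5, seed=42):
    spec = GridSpec(origin_lon=17.0, origin_lat=58.75, n_lon=3, n_lat=3)
    scenario = ClimateScenario(
        annual_mean=6.9, daily_noise_sd=0.0, year_anomaly_sd=1.5,
        years=range(2003, 2011), seed=seed,
    )
    grid = simulate_temperature(scenario, spec)
    observer = ObserverModel(mode=SVA, observers_per_cell=1,
                             sva_offset_sd=0.0, seed=7)
    sightings, truth = simulate_sightings_sva(grid, dd_c, t0, observer)
    region = Region("R", frozenset(spec.all_cells()))
    ff = build_ff_dataset(dedupe_location_year(sightings), spec, region, SVA)
    return grid, region, ff, truth


class TestPrimaryRange:
    def test_single_observation_degenerate(self, small_spec, small_region):
        from phenodd import FFDataset, FFObservation
        from phenodd.degree_days import RegionalDDTable
        cum = np.linspace(1, 400, 365)
        table = RegionalDDTable(region="toy", t0=5.5, years={2005: cum})
        obs = FFObservation(cell=(0, 0), year=2005, day_of_year=150,
                            location=(10.1, 55.1))
        ds = FFDataset(assumption=SVA, region="toy", observations=[obs])
        lo, mean, hi = primary_ddc_range(ds, table)
        assert lo == mean == hi == pytest.approx(cum[149])

    def test_two_year_arithmetic(self):
        from phenodd import FFDataset, FFObservation
        from phenodd.degree_days import RegionalDDTable
        table = RegionalDDTable(
            region="toy", t0=5.5,
            years={2003: np.arange(1.0, 366.0), 2004: np.arange(1.0, 367.0)},
        )
        obs = [
            FFObservation(cell=(0, 0), year=2003, day_of_year=140,
                          location=(10.1, 55.1)),
            FFObservation(cell=(0, 0), year=2004, day_of_year=160,
                          location=(10.1, 55.1)),
        ]
        ds = FFDataset(assumption=SVA, region="toy", observations=obs)
        assert primary_ddc_range(ds, table) == (140.0, 150.0, 160.0)

    def test_brackets_calibrated_optimum_noiseless(self):
        grid, region, ff, truth = _noiseless_world()
        table = regional_table(grid, region, ff.years, 5.5)
        lo, _, hi = primary_ddc_range(ff, table)
        curve = calibrate_region(ff, table)
        assert lo - 1 <= curve.best_dd_c <= hi + 1


class TestCalibrate:
    def test_noiseless_recovery_exact(self):
        grid, region, ff, truth = _noiseless_world(dd_c=160.0)
        table = regional_table(grid, region, ff.years, 5.5)
        curve = calibrate_region(ff, table)
        assert curve.best_rmse == 0.0
        assert abs(curve.best_dd_c - 160.0) <= 1.0

    def test_later_observations_weakly_increase_ddc(self):
        grid, region, ff, truth = _noiseless_world()
        table = regional_table(grid, region, ff.years, 5.5)
        from phenodd.observations import regional_annual_mean_ff
        observed = regional_annual_mean_ff(ff)
        search = DDCSearchGrid(lo=100, hi=260)
        base = calibrate(observed, table, search).best_dd_c
        shifted = {y: d + 5 for y, d in observed.items()}
        later = calibrate(shifted, table, search).best_dd_c
        assert later >= base

    def test_tie_breaks_to_smaller_ddc(self):
        from phenodd.degree_days import RegionalDDTable
        # a big day-100 increment: dd_c in [100, 110] all cross on day 100
        cum = np.arange(1.0, 366.0)
        cum[99:] += 10.0
        table = RegionalDDTable(region="r", t0=5.5, years={2003: cum})
        curve = calibrate({2003: 100}, table, DDCSearchGrid(lo=50, hi=150))
        assert curve.best_rmse == 0.0
        assert curve.best_dd_c == 100.0  # smallest dd_c on the tied plateau

    def test_boundary_argmin_extends_once(self):
        from phenodd.degree_days import RegionalDDTable
        # every candidate crosses on the same day: ties all the way down
        cum = np.concatenate([np.zeros(99), np.full(266, 200.0)])
        table = RegionalDDTable(region="r", t0=5.5, years={2003: cum})
        curve = calibrate({2003: 100}, table, DDCSearchGrid(lo=50, hi=150))
        assert curve.boundary_extended
        assert curve.best_rmse == 0.0

    def test_unreachable_candidates_excluded(self):
        from phenodd.degree_days import RegionalDDTable
        table = RegionalDDTable(region="r", t0=5.5,
                                years={2003: np.arange(1.0, 366.0)})
        with pytest.raises(DataError):
            calibrate({2003: 100}, table, DDCSearchGrid(lo=400, hi=450))


class TestSelectBestModel:
    def c(self, t0, dd_c, rmse):
        return RMSECurve(t0=t0, dd_c_values=np.array([dd_c]),
                         rmse_values=np.array([rmse]), best_dd_c=dd_c,
                         best_rmse=rmse)

    def test_single_curve(self):
        assert select_best_model([self.c(5.5, 160, 2.0)]) == ModelSpec(160, 5.5)

    def test_lower_rmse_wins(self):
        best = select_best_model([self.c(5.5, 160, 6.0), self.c(0.0, 300, 5.0)])
        assert best == ModelSpec(300, 0.0)

    def test_tie_breaks_to_smaller_t0(self):
        best = select_best_model([self.c(5.5, 160, 5.0), self.c(5.0, 170, 5.0)])
        assert best.t0 == 5.0


class TestConsistencyMetrics:
    def test_cross_regional_spread_sva(self):
        m = consistency_metrics({"SVA": {"north": 167, "mid": 184, "south": 188}})
        assert m.per_case["SVA"].mid_range == pytest.approx(177.5)
        assert m.per_case["SVA"].half_range_pct_rounded == 6

    def test_cross_regional_spread_oba(self):
        m = consistency_metrics({"OBA": {"north": 147, "mid": 159, "south": 153}})
        assert m.per_case["OBA"].mid_range == pytest.approx(153.0)
        assert m.per_case["OBA"].half_range_pct_rounded == 4

    def test_pooled_across_cases(self):
        m = consistency_metrics({
            "SVA": {"n": 167, "m": 184, "s": 188},
            "OBA": {"n": 147, "m": 159, "s": 153},
        })
        assert m.pooled.half_range_pct_rounded == 12

    def test_identical_values(self):
        m = consistency_metrics({"X": {"a": 150, "b": 150}})
        assert m.per_case["X"].mid_range == 150
        assert m.per_case["X"].half_range_pct == 0.0

    def test_single_region_rejected(self):
        with pytest.raises(DataError):
            consistency_metrics({"X": {"a": 150}})


class TestPointTest:
    def test_exact_observations_zero_rmse(self):
        grid, region, ff, truth = _noiseless_world()
        series = [accumulate(grid, cell, year, 5.5)
                  for cell in sorted(region.cells) for year in ff.years]
        model = ModelSpec(dd_c=160.0, t0=5.5)
        assert point_test(model, series, ff) == 0.0

    def test_symmetric_offsets(self):
        from phenodd import FFDataset, FFObservation
        from phenodd.degree_days import DDSeries
        cum = np.arange(1.0, 366.0)
        series = [DDSeries(cell=(0, 0), year=2003, t0=5.5, cumulative=cum)]
        obs = [
            FFObservation(cell=(0, 0), year=2003, day_of_year=103,
                          location=(10.1, 55.1)),
            FFObservation(cell=(0, 0), year=2003, day_of_year=97,
                          location=(10.2, 55.1)),
        ]
        ds = FFDataset(assumption=SVA, region="r", observations=obs)
        assert point_test(ModelSpec(100.0, 5.5), series, ds) == pytest.approx(3.0)

    def test_t0_mismatch_rejected(self):
        from phenodd.degree_days import DDSeries
        from phenodd import FFDataset
        series = [DDSeries(cell=(0, 0), year=2003, t0=0.0,
                           cumulative=np.arange(1.0, 366.0))]
        ds = FFDataset(assumption=SVA, region="r")
        with pytest.raises(ValueError, match="t0"):
            point_test(ModelSpec(100.0, 5.5), series, ds)

    def test_point_rmse_grows_with_offset_sd(self):
        spec = GridSpec(origin_lon=17.0, origin_lat=58.75, n_lon=3, n_lat=3)
        scenario = ClimateScenario(annual_mean=6.9, years=range(2003, 2008),
                                   seed=9)
        grid = simulate_temperature(scenario, spec)
        region = Region("R", frozenset(spec.all_cells()))
        rmses = []
        for sd in (0.2, 1.0):
            observer = ObserverModel(mode=SVA, observers_per_cell=4,
                                     sva_offset_sd=sd, seed=11)
            sightings, _ = simulate_sightings_sva(grid, 160.0, 5.5, observer)
            ff = build_ff_dataset(dedupe_location_year(sightings), spec,
                                  region, SVA)
            series = [accumulate(grid, cell, year, 5.5)
                      for cell in sorted(region.cells) for year in ff.years]
            rmses.append(point_test(ModelSpec(160.0, 5.5), series, ff))
        assert rmses[1] > rmses[0]
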