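"""End-to-end orchestration used by the command-line interface.

Each stage reads/writes the package's plain formats so a run is fully
reproducible from its output directory: ``simulate`` writes per-region
temperature NetCDF, sighting CSVs (one per observation mechanism), the
truth JSON and a regions JSON; ``calibrate`` turns those into per-region,
per-assumption RMSE curves, best models and cross-regional consistency
metrics; ``point_test`` scores best models against individual sightings;
``change`` produces the two-period assessment.  Every stage writes a
manifest (config echo + package version) sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate_change import PeriodDefinition, assess_change
from .config import RunConfig
from .degree_days import (
    WHOLE_YEAR,
    accumulate,
    regional_table,
    t0_scan,
    t0_values,
    write_regional_dd_csv,
)
from .errors import ConfigError, DataError
from .ff_model import (
    ModelSpec,
    calibrate_region,
    consistency_metrics,
    point_test,
    select_best_model,
)
from .observations import OBA, SVA, build_ff_dataset, dedupe_location_year
from .synthetic_data import (
    ClimateScenario,
    ObserverModel,
    paper_like_scenarios,
    simulate_sightings_oba,
    simulate_sightings_sva,
    simulate_temperature,
)
from .temperature_io import (
    GridSpec,
    Region,
    read_regions_json,
    read_sightings_csv,
    read_temperature_netcdf,
    write_regions_json,
    write_sightings_csv,
    write_temperature_netcdf,
)

logger = logging.getLogger(__name__)

_CASE_NAMES = {"sva": SVA, "oba": OBA}


def _write_manifest(out_dir: Path, cfg: RunConfig, stage: str) -> None:
    payload = {"stage": stage, "package_version": __version__, "config": cfg.echo()}
    with open(out_dir / f"manifest_{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=str)


def _region_setups(cfg: RunConfig) -> dict[str, tuple[GridSpec, ClimateScenario]]:
    years = tuple(range(cfg.climate_years[0], cfg.climate_years[1] + 1))
    if cfg.regions is None:
        setups = paper_like_scenarios(seed=cfg.seed, years=years)
        if cfg.warming_per_period:
            for spec, scenario in setups.values():
                scenario.warming_per_period = cfg.warming_per_period
        return setups
    setups = {}
    for k, (name, block) in enumerate(sorted(cfg.regions.items())):
        block = dict(block)
        grid = block.pop("grid", {})
        try:
            spec = GridSpec(
                origin_lon=grid.get("origin_lon", 13.0),
                origin_lat=grid.get("origin_lat", 55.25),
                n_lon=grid.get("n_lon", 3),
                n_lat=grid.get("n_lat", 3),
                cell_size=grid.get("cell_size", 0.25),
            )
            scenario = ClimateScenario(
                years=years,
                seed=(cfg.seed * 7919 + k) % (2**31),
                warming_per_period=cfg.warming_per_period,
                **block,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"region {name!r}: {exc}") from exc
        setups[name] = (spec, scenario)
    return setups


def run_simulate(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Generate temperature, sightings and truth files for every region."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setups = _region_setups(cfg)
    regions = {}
    truth_payload: dict = {
        "dd_c_true": cfg.dd_c_true, "t0_true": cfg.t0_true, "regions": {}
    }
    y0, y1 = cfg.sighting_years
    for k, (name, (spec, scenario)) in enumerate(setups.items()):
        grid = simulate_temperature(scenario, spec)
        write_temperature_netcdf(grid, out / f"{name}_temperature.nc")
        regions[name] = Region(name=name, cells=frozenset(spec.all_cells()))
        region_truth = {}
        mask = (grid.dates.year >= y0) & (grid.dates.year <= y1)
        window = type(grid)(
            spec=grid.spec, dates=grid.dates[mask],
            tmax=grid.tmax[mask], tmin=grid.tmin[mask],
        )
        for c, case in enumerate(cfg.assumptions):
            observer = ObserverModel(
                mode=_CASE_NAMES[case],
                seed=(cfg.seed * 104729 + 17 * k + 3 * c) % (2**31),
                **cfg.observer,
            )
            simulate = (
                simulate_sightings_sva if case == "sva" else simulate_sightings_oba
            )
            sightings, truth = simulate(window, cfg.dd_c_true, cfg.t0_true, observer)
            write_sightings_csv(sightings, out / f"{name}_sightings_{case}.csv")
            region_truth[case] = {
                f"{cell[0]},{cell[1]},{year}": day
                for (cell, year), day in truth.ff.items()
            }
        truth_payload["regions"][name] = region_truth
        logger.info("simulated region %s: %d cells, years %d-%d",
                    name, spec.n_lon * spec.n_lat, scenario.years[0],
                    scenario.years[-1])
    write_regions_json(regions, out / "regions.json")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_payload, fh, indent=1)
    _write_manifest(out, cfg, "simulate")
    return {"out_dir": str(out), "regions": sorted(regions)}


def _load_inputs(cfg: RunConfig):
    if cfg.data_dir is None:
        raise ConfigError("data_dir must point at a simulate output directory")
    data = Path(cfg.data_dir)
    if not data.is_dir():
        raise ConfigError(f"data_dir {data} does not exist")
    regions = read_regions_json(data / "regions.json")
    return data, regions


def run_calibrate(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Calibrate per region and assumption across the t0 scan."""
    data, regions = _load_inputs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan = cfg.t0_scan
    report: dict = {"species": cfg.species, "regions": {}, "consistency": {}}
    curve_rows = []
    tables_for_export = []
    best_by_case: dict[str, dict[str, float]] = {c: {} for c in cfg.assumptions}
    for name, region in sorted(regions.items()):
        grid = read_temperature_netcdf(data / f"{name}_temperature.nc")
        report["regions"][name] = {}
        for case in cfg.assumptions:
            records = read_sightings_csv(
                data / f"{name}_sightings_{case}.csv", species_filter=cfg.species
            )
            records = dedupe_location_year(records)
            ff_ds = build_ff_dataset(records, grid.spec, region, _CASE_NAMES[case])
            if not ff_ds.observations:
                raise DataError(f"region {name}/{case}: no usable sightings")
            logger.info("region %s/%s: %d records -> %d FF observations",
                        name, case, len(records), len(ff_ds))
            years = ff_ds.years
            tables = t0_scan(grid, region, years,
                             scan["min"], scan["max"], scan["step"])
            tables_for_export.extend(tables.values())
            curves = {}
            for t0, table in tables.items():
                curve = calibrate_region(ff_ds, table, ddc_step=cfg.ddc_step)
                curves[t0] = curve
                for dd_c, rmse in zip(curve.dd_c_values, curve.rmse_values):
                    curve_rows.append(
                        (name, case, t0, float(dd_c),
                         float(rmse) if np.isfinite(rmse) else "")
                    )
            best = select_best_model(curves.values())
            best_by_case[case][name] = best.dd_c
            report["regions"][name][case] = {
                "best": {
                    "dd_c": best.dd_c,
                    "t0": best.t0,
                    "rmse_days": curves[best.t0].best_rmse,
                },
                "per_t0": {
                    str(t0): {"dd_c": c.best_dd_c, "rmse_days": c.best_rmse,
                              "boundary_extended": c.boundary_extended}
                    for t0, c in curves.items()
                },
                "n_observations": len(ff_ds),
            }
    for case, values in best_by_case.items():
        if len(values) >= 2:
            metrics = consistency_metrics({case: values})
            report["consistency"][case] = {
                "mid_range_dd_c": metrics.per_case[case].mid_range,
                "half_range_pct": metrics.per_case[case].half_range_pct,
                "half_range_pct_rounded":
                    metrics.per_case[case].half_range_pct_rounded,
            }
    pooled_input = {c: v for c, v in best_by_case.items() if len(v) >= 2}
    if pooled_input:
        pooled = consistency_metrics(pooled_input).pooled
        report["consistency"]["pooled"] = {
            "mid_range_dd_c": pooled.mid_range,
            "half_range_pct": pooled.half_range_pct,
            "half_range_pct_rounded": pooled.half_range_pct_rounded,
        }
    with open(out / "calibration.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    pd.DataFrame(
        curve_rows, columns=["region", "assumption", "t0", "dd_c", "rmse_days"]
    ).to_csv(out / "rmse_curves.csv", index=False)
    write_regional_dd_csv(tables_for_export, out / "regional_dd.csv")
    _write_manifest(out, cfg, "calibrate")
    return report


def _best_model(cfg: RunConfig, calibration: dict | None,
                region: str, case: str) -> ModelSpec:
    if cfg.model is not None:
        return ModelSpec(dd_c=float(cfg.model["dd_c"]), t0=float(cfg.model["t0"]))
    if calibration is None:
        raise ConfigError("provide a calibration report or an explicit model block")
    try:
        block = calibration["regions"][region][case]["best"]
    except KeyError as exc:
        raise DataError(
            f"calibration report lacks region {region!r} case {case!r}"
        ) from exc
    return ModelSpec(dd_c=block["dd_c"], t0=block["t0"])


def run_point_test(cfg: RunConfig, out_dir: str | Path,
                   calibration: dict | None = None) -> dict:
    """Score best models against every individual sighting per cell-year."""
    data, regions = _load_inputs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for name, region in sorted(regions.items()):
        grid = read_temperature_netcdf(data / f"{name}_temperature.nc")
        results[name] = {}
        for case in cfg.assumptions:
            model = _best_model(cfg, calibration, name, case)
            records = dedupe_location_year(
                read_sightings_csv(
                    data / f"{name}_sightings_{case}.csv",
                    species_filter=cfg.species,
                )
            )
            ff_ds = build_ff_dataset(records, grid.spec, region, _CASE_NAMES[case])
            series = [
                accumulate(grid, cell, year, model.t0)
                for cell in sorted(region.cells)
                for year in sorted({o.year for o in ff_ds.observations})
            ]
            results[name][case] = {
                "model": {"dd_c": model.dd_c, "t0": model.t0},
                "point_rmse_days": point_test(model, series, ff_ds),
                "n_observations": len(ff_ds),
            }
    with open(out / "point_test.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1)
    _write_manifest(out, cfg, "point_test")
    return results


def run_change(cfg: RunConfig, out_dir: str | Path,
               calibration: dict | None = None) -> dict:
    """Two-period change assessment per region and assumption."""
    data, regions = _load_inputs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(cfg.periods) != 2:
        raise ConfigError("change assessment needs exactly two periods")
    p1 = PeriodDefinition(cfg.periods[0]["name"], cfg.periods[0]["start"],
                          cfg.periods[0]["end"])
    p2 = PeriodDefinition(cfg.periods[1]["name"], cfg.periods[1]["start"],
                          cfg.periods[1]["end"])
    scan = cfg.t0_scan
    results: dict = {}
    rows = []
    for name, region in sorted(regions.items()):
        grid = read_temperature_netcdf(data / f"{name}_temperature.nc")
        covered = set(grid.years)
        wanted = set(p1.years) | set(p2.years)
        if not wanted <= covered:
            raise DataError(
                f"region {name}: temperature data lacks period years "
                f"{sorted(wanted - covered)}"
            )
        results[name] = {}
        for case in cfg.assumptions:
            model = _best_model(cfg, calibration, name, case)
            table = regional_table(grid, region, sorted(wanted), model.t0)
            assessment = assess_change(
                name, model, table, grid, region, p1, p2,
                t0_set=t0_values(scan["min"], scan["max"], scan["step"]),
            )
            results[name][case] = {
                "model": {"dd_c": model.dd_c, "t0": model.t0},
                "mean_ff_period1": assessment.mean_ff_period1,
                "mean_ff_period2": assessment.mean_ff_period2,
                "ff_advancement_days": assessment.ff_advancement_days,
                "delta_t_mean": assessment.delta_t_mean,
                "delta_dd": {
                    str(t0): {
                        "jul31": windows[(7, 31)],
                        "annual": windows[WHOLE_YEAR],
                    }
                    for t0, windows in assessment.delta_dd.items()
                },
            }
            for t0, windows in assessment.delta_dd.items():
                rows.append((name, case, p1.name, p2.name,
                             assessment.ff_advancement_days,
                             assessment.delta_t_mean, t0,
                             windows[(7, 31)], windows[WHOLE_YEAR]))
    with open(out / "change.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1)
    pd.DataFrame(
        rows,
        columns=["region", "assumption", "period1", "period2",
                 "ff_advancement_days", "delta_t_mean", "t0",
                 "delta_dd_jul31", "delta_dd_annual"],
    ).to_csv(out / "change.csv", index=False)
    _write_manifest(out, cfg, "change")
    return results
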