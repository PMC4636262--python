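"""Gridded temperature, sighting and region I/O.

Temperature lives on a regular lon/lat grid (E-OBS-like, 0.25° cells by
default) as daily maximum/minimum series per cell.  Sightings are point
records (species, date, lon, lat) in the style of citizen-science occurrence
exports.  Regions are named sets of grid cells.

Conventions
-----------
* Cell indices are 0-based; cell boundaries are half-open ``[min, max)`` in
  both lon and lat, so a point exactly on the grid's outer maximum edge is
  outside the grid.
* Missing temperature values are represented as NaN and never silently
  filled; downstream degree-day accumulation refuses incomplete cell-years.
* CSV dialects are comma-separated UTF-8 with "." decimal separator.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import EmptyGridError, FormatError

logger = logging.getLogger(__name__)

Cell = tuple[int, int]  # (lon_index, lat_index)

#: Default E-OBS variable names: daily maximum (tx) and minimum (tn).
DEFAULT_VARIABLES = ("tx", "tn")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon``/``origin_lat`` are the coordinates of the *lower-left
    corner* of cell (0, 0), not its center.
    """

    origin_lon: float
    origin_lat: float
    n_lon: int
    n_lat: int
    cell_size: float = 0.25

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.origin_lat + self.cell_size * (np.arange(self.n_lat) + 0.5)

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        i, j = cell
        return (
            self.origin_lon + self.cell_size * (i + 0.5),
            self.origin_lat + self.cell_size * (j + 0.5),
        )

    def contains_cell(self, cell: Cell) -> bool:
        i, j = cell
        return 0 <= i < self.n_lon and 0 <= j < self.n_lat

    def all_cells(self) -> list[Cell]:
        return [(i, j) for j in range(self.n_lat) for i in range(self.n_lon)]


def assign_cell(lon: float, lat: float, spec: GridSpec) -> Cell | None:
    """Map a point to its grid cell, or ``None`` if outside the extent.

    Half-open convention: point p lies in cell i iff
    ``origin + i*cell_size <= p < origin + (i+1)*cell_size``.
    """
    i = math.floor((lon - spec.origin_lon) / spec.cell_size)
    j = math.floor((lat - spec.origin_lat) / spec.cell_size)
    if 0 <= i < spec.n_lon and 0 <= j < spec.n_lat:
        return (i, j)
    return None


@dataclass
class TemperatureGrid:
    """Daily tmax/tmin series for every cell of a regular grid.

    Arrays are shaped ``(n_days, n_lat, n_lon)`` in °C with NaN marking
    missing values.  The calendar must be contiguous daily.
    """

    spec: GridSpec
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        expected = (len(self.dates), self.spec.n_lat, self.spec.n_lon)
        if self.tmax.shape != expected or self.tmin.shape != expected:
            raise ValueError(
                f"temperature arrays must have shape {expected}, "
                f"got {self.tmax.shape} / {self.tmin.shape}"
            )
        if len(self.dates) > 1:
            steps = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(steps == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly increasing daily")
        both = ~np.isnan(self.tmax) & ~np.isnan(self.tmin)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise ValueError("tmax < tmin at some grid points")

    @property
    def years(self) -> list[int]:
        return sorted(set(self.dates.year))

    def year_mask(self, year: int) -> np.ndarray:
        return (self.dates.year == year).to_numpy() \
            if hasattr(self.dates.year, "to_numpy") else self.dates.year == year

    def cell_series(self, cell: Cell) -> tuple[np.ndarray, np.ndarray]:
        """Full (tmax, tmin) daily series for one cell."""
        i, j = cell
        return self.tmax[:, j, i], self.tmin[:, j, i]

    def cell_year(self, cell: Cell, year: int) -> tuple[np.ndarray, np.ndarray]:
        """(tmax, tmin) for one cell restricted to one calendar year."""
        i, j = cell
        m = self.dates.year == year
        return self.tmax[m, j, i], self.tmin[m, j, i]


def write_temperature_netcdf(
    grid: TemperatureGrid,
    path: str | Path,
    variable_names: Sequence[str] = DEFAULT_VARIABLES,
) -> None:
    """Write a grid as NetCDF3 with (time, latitude, longitude) dimensions."""
    vmax, vmin = variable_names
    ds = xr.Dataset(
        {
            vmax: (("time", "latitude", "longitude"), grid.tmax),
            vmin: (("time", "latitude", "longitude"), grid.tmin),
        },
        coords={
            "time": grid.dates,
            "latitude": grid.spec.lat_centers,
            "longitude": grid.spec.lon_centers,
        },
        attrs={
            "cell_size": grid.spec.cell_size,
            "origin_lon": grid.spec.origin_lon,
            "origin_lat": grid.spec.origin_lat,
        },
    )
    ds[vmax].attrs["units"] = "degC"
    ds[vmin].attrs["units"] = "degC"
    ds.to_netcdf(path, engine="scipy")


def read_temperature_netcdf(
    path: str | Path,
    variable_names: Sequence[str] = DEFAULT_VARIABLES,
    bbox: tuple[float, float, float, float] | None = None,
) -> TemperatureGrid:
    """Read a daily tmax/tmin NetCDF file, optionally restricted to a bbox.

    Parameters
    ----------
    variable_names
        ``(tmax_name, tmin_name)``; defaults to E-OBS ``("tx", "tn")``.
    bbox
        ``(lon_min, lon_max, lat_min, lat_max)``; cells are kept when their
        *center* falls inside the (closed) box.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        vmax, vmin = variable_names
        for name in (vmax, vmin):
            if name not in ds.variables:
                raise FormatError(f"variable {name!r} not found in {path}")
            if ds[name].dims != ("time", "latitude", "longitude"):
                raise FormatError(
                    f"variable {name!r} must have dims "
                    f"(time, latitude, longitude), got {ds[name].dims}"
                )
        times = pd.DatetimeIndex(ds["time"].values)
        if len(times) > 1:
            steps = np.diff(times.values).astype("timedelta64[D]")
            if not np.all(steps == np.timedelta64(1, "D")):
                raise FormatError(f"time axis of {path} is not contiguous daily")

        lons = np.asarray(ds["longitude"].values, dtype=float)
        lats = np.asarray(ds["latitude"].values, dtype=float)
        if "cell_size" in ds.attrs:
            cell = float(ds.attrs["cell_size"])
        elif len(lons) > 1:
            cell = float(lons[1] - lons[0])
        elif len(lats) > 1:
            cell = float(lats[1] - lats[0])
        else:
            raise FormatError(f"{path}: cannot infer cell size from a 1-cell grid")

        keep_lon = np.ones(len(lons), dtype=bool)
        keep_lat = np.ones(len(lats), dtype=bool)
        if bbox is not None:
            lon_min, lon_max, lat_min, lat_max = bbox
            keep_lon = (lons >= lon_min) & (lons <= lon_max)
            keep_lat = (lats >= lat_min) & (lats <= lat_max)
            if not keep_lon.any() or not keep_lat.any():
                raise EmptyGridError(f"bbox {bbox} covers no cells of {path}")

        lons, lats = lons[keep_lon], lats[keep_lat]
        spec = GridSpec(
            origin_lon=float(lons[0]) - cell / 2,
            origin_lat=float(lats[0]) - cell / 2,
            n_lon=len(lons),
            n_lat=len(lats),
            cell_size=cell,
        )
        tmax = np.asarray(ds[vmax].values, dtype=float)[:, keep_lat][:, :, keep_lon]
        tmin = np.asarray(ds[vmin].values, dtype=float)[:, keep_lat][:, :, keep_lon]
    return TemperatureGrid(spec=spec, dates=times, tmax=tmax, tmin=tmin)


def write_temperature_csv(grid: TemperatureGrid, path: str | Path) -> None:
    """Long-format CSV: cell_lon_index, cell_lat_index, date, tmax, tmin."""
    n_days = len(grid.dates)
    rows = []
    for i in range(grid.spec.n_lon):
        for j in range(grid.spec.n_lat):
            rows.append(
                pd.DataFrame(
                    {
                        "cell_lon_index": i,
                        "cell_lat_index": j,
                        "date": grid.dates.strftime("%Y-%m-%d"),
                        "tmax": grid.tmax[:, j, i],
                        "tmin": grid.tmin[:, j, i],
                    },
                    index=range(n_days),
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_temperature_csv(path: str | Path, spec: GridSpec) -> TemperatureGrid:
    """Read the long-format temperature CSV back onto a known grid geometry."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"cell_lon_index", "cell_lat_index", "date", "tmax", "tmin"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    day_pos = {d: k for k, d in enumerate(dates)}
    tmax = np.full((len(dates), spec.n_lat, spec.n_lon), np.nan)
    tmin = np.full_like(tmax, np.nan)
    for row in df.itertuples(index=False):
        k = day_pos[row.date]
        tmax[k, row.cell_lat_index, row.cell_lon_index] = row.tmax
        tmin[k, row.cell_lat_index, row.cell_lon_index] = row.tmin
    return TemperatureGrid(spec=spec, dates=dates, tmax=tmax, tmin=tmin)


@dataclass(frozen=True)
class SightingRecord:
    """One occurrence report: a species seen on a date at a point."""

    species: str
    date: Date
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError("sighting coordinates must be finite")


def read_sightings_csv(
    path: str | Path, species_filter: str | None = None
) -> list[SightingRecord]:
    """Read a sightings CSV (columns species, date, lon, lat).

    Dates must be ISO 8601 (``YYYY-MM-DD``); an unparseable date raises a
    :class:`FormatError` citing the offending line number (1-based, header
    is line 1).
    """
    records: list[SightingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "date", "lon", "lat"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: expected header with columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if species_filter is not None and row["species"] != species_filter:
                continue
            try:
                when = Date.fromisoformat(row["date"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: bad date {row['date']!r}"
                ) from exc
            try:
                lon, lat = float(row["lon"]), float(row["lat"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: bad coordinates"
                ) from exc
            records.append(SightingRecord(row["species"], when, lon, lat))
    return records


def write_sightings_csv(records: Iterable[SightingRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "date", "lon", "lat"])
        for r in records:
            writer.writerow([r.species, r.date.isoformat(), repr(r.lon), repr(r.lat)])


@dataclass
class Region:
    """A named, non-empty set of grid cells."""

    name: str
    cells: frozenset[Cell] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.cells = frozenset(tuple(c) for c in self.cells)
        if not self.cells:
            raise ValueError(f"region {self.name!r} has no cells")

    def validate_against(self, spec: GridSpec) -> None:
        bad = [c for c in self.cells if not spec.contains_cell(c)]
        if bad:
            raise ValueError(f"region {self.name!r} has out-of-grid cells {bad}")


def read_regions_json(path: str | Path) -> dict[str, Region]:
    """Region file: JSON mapping region name -> list of [lon_index, lat_index]."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path}: expected a JSON object of name -> cell list")
    return {
        name: Region(name=name, cells=frozenset((int(i), int(j)) for i, j in cells))
        for name, cells in raw.items()
    }


def write_regions_json(regions: Mapping[str, Region], path: str | Path) -> None:
    payload = {
        name: sorted([list(c) for c in region.cells])
        for name, region in regions.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
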