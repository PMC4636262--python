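"""Degree-day accumulation.

A day's heat contribution above a base (threshold) temperature ``t0`` is
computed from daily maximum and minimum temperature with the UK Met Office
weighted four-branch rule:

====================================  =================================
condition                             daily contribution ΔDD
====================================  =================================
``tmax <= t0``                        0
``tmin >= t0``                        ``tmean - t0``
``tmean >= t0`` and ``tmin < t0``     ``0.5(tmax-t0) - 0.25(t0-tmin)``
``tmean < t0`` and ``tmax > t0``      ``0.25(tmax-t0)``
====================================  =================================

with ``tmean = 0.5(tmax + tmin)``.  The rule is continuous across branch
boundaries and non-negative whenever ``tmax >= tmin``.

Cumulative degree-days always accumulate from January 1 within a calendar
year (no carry-over); Feb 29 is a real day and is included in leap years.
Regional series are the day-wise arithmetic mean of member-cell cumulative
series (an average of degree-days, not the degree-days of an average
temperature).
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .temperature_io import Cell, Region, TemperatureGrid

logger = logging.getLogger(__name__)

#: The full-year accumulation window (through Dec 31).
WHOLE_YEAR = "year-end"


def daily_delta_dd(tmax, tmin, t0):
    """Daily degree-day contribution; accepts scalars or arrays.

    Raises ``ValueError`` if any ``tmax < tmin``.  NaN inputs yield NaN.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    both = ~np.isnan(tmax) & ~np.isnan(tmin)
    if np.any(tmax[both] < tmin[both]):
        raise ValueError("tmax < tmin")
    tmean = 0.5 * (tmax + tmin)
    out = np.select(
        [
            tmax <= t0,
            tmin >= t0,
            (tmean >= t0) & (tmin < t0),
            (tmean < t0) & (tmax > t0),
        ],
        [
            np.zeros_like(tmean),
            tmean - t0,
            0.5 * (tmax - t0) - 0.25 * (t0 - tmin),
            0.25 * (tmax - t0),
        ],
        default=np.nan,
    )
    out = np.where(both, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass
class DDSeries:
    """Cumulative degree-days for one cell and year.

    ``cumulative[d-1]`` is the total accumulated from Jan 1 through
    day-of-year ``d``; the vector has 365 or 366 entries matching the year.
    """

    cell: Cell
    year: int
    t0: float
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if len(self.cumulative) != days_in_year(self.year):
            raise ValueError(
                f"series length {len(self.cumulative)} does not match "
                f"year {self.year}"
            )
        if self.cumulative[0] < 0 or np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative series must be non-negative and non-decreasing")


def accumulate(grid: TemperatureGrid, cell: Cell, year: int, t0: float) -> DDSeries:
    """Cumulative degree-days for one cell-year, from Jan 1 onward.

    A cell-year with any missing (NaN) tmax/tmin is refused with
    :class:`MissingDataError` — no gap-filling.
    """
    tmax, tmin = grid.cell_year(cell, year)
    n = days_in_year(year)
    if len(tmax) != n:
        raise MissingDataError(
            f"cell {cell} year {year}: {len(tmax)} of {n} days present"
        )
    if np.any(np.isnan(tmax)) or np.any(np.isnan(tmin)):
        raise MissingDataError(f"cell {cell} year {year} has missing temperature days")
    return DDSeries(cell=cell, year=year, t0=t0,
                    cumulative=np.cumsum(daily_delta_dd(tmax, tmin, t0)))


@dataclass
class RegionalDDTable:
    """Daily regional-average cumulative degree-days, per year, for one t0."""

    region: str
    t0: float
    years: dict[int, np.ndarray] = field(default_factory=dict)

    def cum(self, year: int) -> np.ndarray:
        if year not in self.years:
            raise MissingDataError(
                f"region {self.region!r} t0={self.t0}: no data for year {year}"
            )
        return self.years[year]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for year in sorted(self.years):
            cum = self.years[year]
            parts.append(
                pd.DataFrame(
                    {
                        "region": self.region,
                        "t0": self.t0,
                        "year": year,
                        "day_of_year": np.arange(1, len(cum) + 1),
                        "cum_dd": cum,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def regional_average(series: Iterable[DDSeries], region: Region) -> RegionalDDTable:
    """Day-wise mean of cell cumulative series across a region, per year."""
    by_year: dict[int, list[DDSeries]] = {}
    t0s = set()
    for s in series:
        if s.cell not in region.cells:
            raise ValueError(f"cell {s.cell} not in region {region.name!r}")
        t0s.add(s.t0)
        by_year.setdefault(s.year, []).append(s)
    if not by_year:
        raise ValueError("no series to average")
    if len(t0s) != 1:
        raise ValueError(f"series mix multiple t0 values: {sorted(t0s)}")
    table = RegionalDDTable(region=region.name, t0=t0s.pop())
    for year, group in by_year.items():
        table.years[year] = np.mean([s.cumulative for s in group], axis=0)
    return table


def fixed_window_dd(
    series: DDSeries | np.ndarray,
    end: tuple[int, int] | str = (7, 31),
    year: int | None = None,
) -> float:
    """Cumulative degree-days at the end of a fixed calendar window.

    ``end`` is a ``(month, day)`` pair (default July 31) or ``WHOLE_YEAR``
    for the Dec-31 total.  When passing a bare vector, ``year`` is needed to
    resolve the month/day into a day-of-year.
    """
    if isinstance(series, DDSeries):
        cum, year = series.cumulative, series.year
    else:
        cum = np.asarray(series, dtype=float)
        if end != WHOLE_YEAR and year is None:
            raise ValueError("year is required to resolve a (month, day) window")
    if end == WHOLE_YEAR:
        return float(cum[-1])
    month, day = end
    doy = Date(year, month, day).timetuple().tm_yday
    if doy > len(cum):
        raise ValueError(f"window end {end} beyond series of length {len(cum)}")
    return float(cum[doy - 1])


def t0_values(t0_min: float = 0.0, t0_max: float = 10.0, step: float = 0.5) -> list[float]:
    """The threshold scan grid, inclusive of both ends (21 values at defaults)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t0_min > t0_max:
        raise ValueError("t0_min must not exceed t0_max")
    n = int(np.floor((t0_max - t0_min) / step + 1e-9)) + 1
    return [round(t0_min + k * step, 10) for k in range(n)]


def regional_table(
    grid: TemperatureGrid,
    region: Region,
    years: Sequence[int],
    t0: float,
    skip_incomplete: bool = True,
) -> RegionalDDTable:
    """Build the regional-average cumulative-DD table for a set of years.

    Cell-years with missing temperature days are excluded (and counted in a
    log line) rather than gap-filled; a year with no complete cell at all is
    omitted from the table.
    """
    region.validate_against(grid.spec)
    table = RegionalDDTable(region=region.name, t0=t0)
    cells = sorted(region.cells)
    n_skipped = 0
    for year in years:
        stack = []
        for cell in cells:
            try:
                stack.append(accumulate(grid, cell, year, t0).cumulative)
            except MissingDataError:
                if not skip_incomplete:
                    raise
                n_skipped += 1
        if stack:
            table.years[year] = np.mean(stack, axis=0)
    if n_skipped:
        logger.info(
            "region %s t0=%s: excluded %d incomplete cell-years",
            region.name, t0, n_skipped,
        )
    return table


def t0_scan(
    grid: TemperatureGrid,
    region: Region,
    years: Sequence[int],
    t0_min: float = 0.0,
    t0_max: float = 10.0,
    step: float = 0.5,
) -> dict[float, RegionalDDTable]:
    """One regional table per threshold in the scan grid."""
    return {
        t0: regional_table(grid, region, years, t0)
        for t0 in t0_values(t0_min, t0_max, step)
    }


def write_regional_dd_csv(
    tables: Iterable[RegionalDDTable], path: str | Path
) -> None:
    """CSV with columns region, t0, year, day_of_year, cum_dd."""
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_regional_dd_csv(path: str | Path) -> dict[tuple[str, float], RegionalDDTable]:
    """Read tables back, keyed by (region, t0)."""
    df = pd.read_csv(path)
    out: dict[tuple[str, float], RegionalDDTable] = {}
    for (region, t0), sub in df.groupby(["region", "t0"], sort=True):
        table = RegionalDDTable(region=str(region), t0=float(t0))
        for year, chunk in sub.groupby("year"):
            chunk = chunk.sort_values("day_of_year")
            table.years[int(year)] = chunk["cum_dd"].to_numpy()
        out[(str(region), float(t0))] = table
    return out
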