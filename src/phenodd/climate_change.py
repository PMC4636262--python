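"""Two-period climate-change assessment.

Compares long-term means between two multi-year periods (canonically
1951–1980 vs 1981–2010): modeled regional-average first-flight dates and
their advancement under warming, the change in regional mean temperature,
and the change in degree-days accumulated over fixed calendar windows
(through July 31, and the whole year) per base temperature.

The interesting contrast these quantities expose: first-flight advancement
across regions need not follow the size of the mean-temperature rise — a
warm region where a small warming converts many days from below to above
the base temperature can advance more than a cold region with a larger
warming mostly "wasted" below the threshold.  Fixed-window degree-day
change tracks advancement; mean-temperature change may not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .degree_days import (
    RegionalDDTable,
    WHOLE_YEAR,
    accumulate,
    fixed_window_dd,
)
from .errors import DataError, MissingDataError
from .ff_model import ModelSpec, model_ff_by_year
from .temperature_io import Region, TemperatureGrid

logger = logging.getLogger(__name__)

#: Default fixed accumulation windows: through July 31, and Dec 31.
DEFAULT_WINDOWS: tuple = ((7, 31), WHOLE_YEAR)


@dataclass(frozen=True)
class PeriodDefinition:
    """An inclusive range of calendar years."""

    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("period start must not exceed end")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


def period_mean_ff(
    model: ModelSpec, dd_table: RegionalDDTable, period: PeriodDefinition
) -> float:
    """Mean modeled first-flight day over the period's years.

    The table must cover every period year; years in which ``dd_c`` is never
    reached are excluded (logged), and all-excluded is an error.
    """
    missing = [y for y in period.years if y not in dd_table.years]
    if missing:
        raise MissingDataError(
            f"DD table for {dd_table.region!r} lacks years {missing}"
        )
    days = model_ff_by_year(dd_table, model.dd_c, period.years)
    n_excluded = len(list(period.years)) - len(days)
    if n_excluded:
        logger.info(
            "period %s: %d not-reached years excluded", period.name, n_excluded
        )
    if not days:
        raise DataError(
            f"dd_c={model.dd_c} reached in no year of period {period.name!r}"
        )
    return float(np.mean(list(days.values())))


def ff_advancement(
    model: ModelSpec,
    dd_table: RegionalDDTable,
    period1: PeriodDefinition,
    period2: PeriodDefinition,
) -> float:
    """Days of first-flight advancement from period1 to period2.

    Positive under warming (period2 earlier than period1).
    """
    return period_mean_ff(model, dd_table, period1) - period_mean_ff(
        model, dd_table, period2
    )


def _period_mean_temperature(
    grid: TemperatureGrid, region: Region, period: PeriodDefinition
) -> float:
    """Mean daily T_mean over all days, cells and years of a period.

    Cell-years containing any missing day are excluded whole (logged).
    """
    total, count, n_excluded = 0.0, 0, 0
    for year in period.years:
        for cell in sorted(region.cells):
            tmax, tmin = grid.cell_year(cell, year)
            if len(tmax) == 0:
                raise MissingDataError(f"year {year} absent from temperature grid")
            tmean = 0.5 * (tmax + tmin)
            if np.any(np.isnan(tmean)):
                n_excluded += 1
                continue
            total += float(tmean.sum())
            count += len(tmean)
    if n_excluded:
        logger.info("period %s: %d incomplete cell-years excluded from "
                    "temperature mean", period.name, n_excluded)
    if count == 0:
        raise DataError(f"no complete cell-years in period {period.name!r}")
    return total / count


def period_temperature_change(
    grid: TemperatureGrid,
    region: Region,
    period1: PeriodDefinition,
    period2: PeriodDefinition,
) -> float:
    """Change (period2 − period1) in regional mean temperature, °C."""
    return _period_mean_temperature(grid, region, period2) - \
        _period_mean_temperature(grid, region, period1)


def _period_mean_window_dd(
    grid: TemperatureGrid,
    region: Region,
    period: PeriodDefinition,
    t0: float,
    window,
) -> float:
    """Period mean of the regional-average fixed-window cumulative DD."""
    per_year: list[float] = []
    n_excluded = 0
    for year in period.years:
        vals = []
        for cell in sorted(region.cells):
            try:
                series = accumulate(grid, cell, year, t0)
            except MissingDataError:
                n_excluded += 1
                continue
            vals.append(fixed_window_dd(series, end=window))
        if vals:
            per_year.append(float(np.mean(vals)))
    if n_excluded:
        logger.info("period %s t0=%s: %d incomplete cell-years excluded",
                    period.name, t0, n_excluded)
    if not per_year:
        raise DataError(f"no complete years in period {period.name!r}")
    return float(np.mean(per_year))


def period_dd_change(
    grid: TemperatureGrid,
    region: Region,
    period1: PeriodDefinition,
    period2: PeriodDefinition,
    t0_set: Sequence[float],
    windows=DEFAULT_WINDOWS,
) -> dict[float, dict]:
    """Change (period2 − period1) in fixed-window DD, per t0 and window.

    Returns ``{t0: {window: delta_dd}}`` with windows keyed as given
    ((month, day) tuples or the whole-year marker).
    """
    out: dict[float, dict] = {}
    for t0 in t0_set:
        out[t0] = {}
        for window in windows:
            m1 = _period_mean_window_dd(grid, region, period1, t0, window)
            m2 = _period_mean_window_dd(grid, region, period2, t0, window)
            out[t0][window] = m2 - m1
    return out


@dataclass
class ChangeAssessment:
    """Everything the two-period comparison produces for one region."""

    region: str
    model: ModelSpec
    period1: PeriodDefinition
    period2: PeriodDefinition
    mean_ff_period1: float
    mean_ff_period2: float
    ff_advancement_days: float
    delta_t_mean: float
    delta_dd: dict[float, dict] = field(default_factory=dict)


def assess_change(
    region_name: str,
    model: ModelSpec,
    dd_table: RegionalDDTable,
    grid: TemperatureGrid,
    region: Region,
    period1: PeriodDefinition,
    period2: PeriodDefinition,
    t0_set: Sequence[float] | None = None,
    windows=DEFAULT_WINDOWS,
) -> ChangeAssessment:
    """Assemble the full two-period assessment for one region."""
    if t0_set is None:
        t0_set = [model.t0]
    m1 = period_mean_ff(model, dd_table, period1)
    m2 = period_mean_ff(model, dd_table, period2)
    return ChangeAssessment(
        region=region_name,
        model=model,
        period1=period1,
        period2=period2,
        mean_ff_period1=m1,
        mean_ff_period2=m2,
        ff_advancement_days=m1 - m2,
        delta_t_mean=period_temperature_change(grid, region, period1, period2),
        delta_dd=period_dd_change(grid, region, period1, period2, t0_set, windows),
    )
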