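"""The first-flight degree-day model and its calibration.

The model posits a species-specific cumulative degree-day requirement
``dd_c`` that is independent of region and climate: first flight happens on
the first day the cumulative degree-day series (above a base temperature
``t0``) reaches ``dd_c``.  Calibration is a grid search over candidate
``dd_c`` values minimising the root-mean-square error (RMSE, in days)
between modeled and observed regional-average first-flight dates across
years; the search is repeated for each base temperature in a scan (0–10 °C
in 0.5 °C steps by default) and the global (t0, dd_c) minimiser selected.

The search range for ``dd_c`` is anchored on the *primary range*: the
minimum / mean / maximum over years of the regional-average cumulative
degree-days evaluated at the observed first-flight dates.  Cross-regional
agreement of the calibrated ``dd_c`` values is summarised by the mid-range
value ``(min+max)/2`` and the half-range as a percent of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .degree_days import DDSeries, RegionalDDTable
from .errors import DataError, MissingDataError, NoCommonYearsError
from .observations import FFDataset, regional_annual_mean_ff
from .temperature_io import Cell

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """A calibrated first-flight model: (degree-day requirement, base temp)."""

    dd_c: float
    t0: float

    def __post_init__(self) -> None:
        if self.dd_c <= 0:
            raise ValueError("dd_c must be positive")


def model_ff_date(cum_dd: np.ndarray, dd_c: float) -> int | None:
    """First day-of-year at which a non-decreasing series reaches ``dd_c``.

    Returns ``None`` when the requirement is never met that year
    (not-reached is a value, not an exception).
    """
    cum_dd = np.asarray(cum_dd)
    idx = int(np.searchsorted(cum_dd, dd_c, side="left"))
    if idx >= len(cum_dd):
        return None
    return idx + 1


def model_ff_by_year(
    table: RegionalDDTable, dd_c: float, years: Iterable[int] | None = None
) -> dict[int, int]:
    """Modeled first-flight day per year; not-reached years are absent."""
    out: dict[int, int] = {}
    for year in sorted(table.years) if years is None else sorted(years):
        day = model_ff_date(table.cum(year), dd_c)
        if day is not None:
            out[year] = day
    return out


def rmse_days(
    model_ff: Mapping[int, float], observed_ff: Mapping[int, float]
) -> float:
    """RMSE over the years present on both sides."""
    common = sorted(set(model_ff) & set(observed_ff))
    if not common:
        raise NoCommonYearsError("model and observations share no years")
    sq = [(model_ff[y] - observed_ff[y]) ** 2 for y in common]
    return math.sqrt(sum(sq) / len(sq))


def primary_ddc_range(
    ff_ds: FFDataset, dd_table: RegionalDDTable
) -> tuple[float, float, float]:
    """(min, mean, max) over years of regional cumulative DD at observed FF.

    Each observation is scored with the *regional-average* cumulative series
    of its year evaluated at its first-flight day; scores are averaged per
    year, then min / mean / max are taken across years.
    """
    if not ff_ds.observations:
        raise DataError("empty FF dataset")
    per_year: dict[int, list[float]] = {}
    for obs in ff_ds.observations:
        cum = dd_table.cum(obs.year)  # raises MissingDataError if absent
        day = min(obs.day_of_year, len(cum))
        per_year.setdefault(obs.year, []).append(float(cum[day - 1]))
    year_means = [float(np.mean(v)) for _, v in sorted(per_year.items())]
    return (min(year_means), float(np.mean(year_means)), max(year_means))


@dataclass
class DDCSearchGrid:
    """Candidate ``dd_c`` values for calibration: ``lo..hi`` inclusive."""

    lo: float
    hi: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.hi < self.lo:
            raise ValueError("invalid dd_c search grid")

    def values(self) -> np.ndarray:
        n = int(math.floor((self.hi - self.lo) / self.step + 1e-9)) + 1
        return self.lo + self.step * np.arange(n)

    @classmethod
    def from_primary_range(
        cls, rng: tuple[float, float, float], step: float = 1.0,
        extend: float = 0.2,
    ) -> "DDCSearchGrid":
        lo = max(step, math.floor(rng[0] * (1 - extend)))
        hi = math.ceil(rng[2] * (1 + extend))
        return cls(lo=lo, hi=hi, step=step)


@dataclass
class RMSECurve:
    """RMSE as a function of candidate ``dd_c`` at a fixed base temperature."""

    t0: float
    dd_c_values: np.ndarray
    rmse_values: np.ndarray
    best_dd_c: float
    best_rmse: float
    boundary_extended: bool = False


# Candidates failing to reach dd_c in more than this fraction of observed
# years are considered invalid and excluded from the arg-min.
MAX_NOT_REACHED_FRAC = 0.5


def _curve_rmse(
    observed_ff: Mapping[int, float],
    dd_table: RegionalDDTable,
    candidates: np.ndarray,
) -> np.ndarray:
    years = sorted(set(observed_ff) & set(dd_table.years))
    if not years:
        raise NoCommonYearsError(
            f"no observed years covered by DD table for region {dd_table.region!r}"
        )
    rmse = np.full(len(candidates), np.inf)
    for k, dd_c in enumerate(candidates):
        model = {}
        for y in years:
            day = model_ff_date(dd_table.years[y], dd_c)
            if day is not None:
                model[y] = day
        if len(model) < len(years) * (1 - MAX_NOT_REACHED_FRAC):
            continue  # invalid candidate: dd_c out of reach in too many years
        if model:
            rmse[k] = rmse_days(model, observed_ff)
    return rmse


def calibrate(
    observed_ff: Mapping[int, float],
    dd_table: RegionalDDTable,
    search: DDCSearchGrid,
) -> RMSECurve:
    """Grid-search ``dd_c`` against observed regional-average FF dates.

    Ties in RMSE resolve to the smaller ``dd_c``.  If the arg-min lands on a
    search boundary the range is extended once by 20% on that side (with a
    logged warning) before reporting.
    """
    grid = search
    for attempt in (0, 1):
        candidates = grid.values()
        rmse = _curve_rmse(observed_ff, dd_table, candidates)
        if not np.isfinite(rmse).any():
            raise DataError(
                f"no valid dd_c candidate in [{grid.lo}, {grid.hi}] for "
                f"t0={dd_table.t0}"
            )
        k = int(np.argmin(rmse))  # first minimum == smallest dd_c on ties
        on_boundary = k == 0 or k == len(candidates) - 1
        if not on_boundary or attempt == 1:
            return RMSECurve(
                t0=dd_table.t0,
                dd_c_values=candidates,
                rmse_values=rmse,
                best_dd_c=float(candidates[k]),
                best_rmse=float(rmse[k]),
                boundary_extended=attempt == 1,
            )
        span = grid.hi - grid.lo
        lo = grid.lo - 0.2 * span if k == 0 else grid.lo
        hi = grid.hi + 0.2 * span if k == len(candidates) - 1 else grid.hi
        logger.warning(
            "t0=%s: dd_c arg-min on search boundary; extending to [%.0f, %.0f]",
            dd_table.t0, lo, hi,
        )
        grid = DDCSearchGrid(lo=max(grid.step, lo), hi=hi, step=grid.step)
    raise AssertionError("unreachable")


def calibrate_region(
    ff_ds: FFDataset,
    dd_table: RegionalDDTable,
    search: DDCSearchGrid | None = None,
    ddc_step: float = 1.0,
) -> RMSECurve:
    """Calibrate one region at the table's t0, defaulting the search grid.

    The default grid is the primary range extended by ±20%, stepped by
    ``ddc_step`` (1 degree-day by default).
    """
    if search is None:
        search = DDCSearchGrid.from_primary_range(
            primary_ddc_range(ff_ds, dd_table), step=ddc_step
        )
    return calibrate(regional_annual_mean_ff(ff_ds), dd_table, search)


@dataclass
class RegionalCalibration:
    """All RMSE curves across the t0 scan for one region and assumption."""

    region: str
    assumption: str
    curves: dict[float, RMSECurve] = field(default_factory=dict)

    @property
    def best(self) -> ModelSpec:
        return select_best_model(self.curves.values())


def select_best_model(curves: Iterable[RMSECurve]) -> ModelSpec:
    """Global (t0, dd_c) RMSE minimiser; ties → smaller t0, then smaller dd_c."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to select from")
    winner = min(curves, key=lambda c: (c.best_rmse, c.t0, c.best_dd_c))
    return ModelSpec(dd_c=winner.best_dd_c, t0=winner.t0)


@dataclass(frozen=True)
class CaseConsistency:
    mid_range: float
    half_range_pct: float

    @property
    def half_range_pct_rounded(self) -> int:
        return round(self.half_range_pct)


@dataclass
class ConsistencyMetrics:
    """Cross-regional spread of best dd_c values, per case and pooled.

    ``mid_range = (min+max)/2`` and the half-range percent is
    ``100 * (max-min)/2 / mid_range`` — i.e. the best values span
    mid-range ± half_range_pct %.
    """

    per_case: dict[str, CaseConsistency]
    pooled: CaseConsistency


def _case(values: Sequence[float]) -> CaseConsistency:
    lo, hi = min(values), max(values)
    mid = 0.5 * (lo + hi)
    pct = 100.0 * (hi - lo) / 2.0 / mid if mid else 0.0
    return CaseConsistency(mid_range=mid, half_range_pct=pct)


def consistency_metrics(
    best_ddc: Mapping[str, Mapping[str, float]]
) -> ConsistencyMetrics:
    """Summarise best dd_c spread from ``{case: {region: dd_c}}``.

    Each case needs at least two regions; the pooled summary spans every
    value across all cases.
    """
    per_case = {}
    pooled_values: list[float] = []
    for case, regional in best_ddc.items():
        values = list(regional.values())
        if len(values) < 2:
            raise DataError(f"case {case!r} needs >= 2 regions")
        per_case[case] = _case(values)
        pooled_values.extend(values)
    return ConsistencyMetrics(per_case=per_case, pooled=_case(pooled_values))


def point_test(
    model: ModelSpec,
    cell_series: Iterable[DDSeries],
    ff_ds: FFDataset,
) -> float:
    """RMSE of per-cell modeled FF against every individual observation.

    Each observation is compared with the first-crossing day of its own
    cell's cumulative series for its year.  Observations whose cell-year
    never reaches ``dd_c`` are excluded (counted in a log line).
    """
    index: dict[tuple[Cell, int], DDSeries] = {}
    for s in cell_series:
        if s.t0 != model.t0:
            raise ValueError(
                f"series t0={s.t0} does not match model t0={model.t0}"
            )
        index[(s.cell, s.year)] = s
    sq: list[float] = []
    n_excluded = 0
    for obs in ff_ds.observations:
        key = (obs.cell, obs.year)
        if key not in index:
            raise MissingDataError(f"no DD series for cell-year {key}")
        day = model_ff_date(index[key].cumulative, model.dd_c)
        if day is None:
            n_excluded += 1
            continue
        sq.append(float(obs.day_of_year - day) ** 2)
    if n_excluded:
        logger.info("point test: %d observations in not-reached cell-years "
                    "excluded", n_excluded)
    if not sq:
        raise DataError("no comparable observations in point test")
    return math.sqrt(sum(sq) / len(sq))
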