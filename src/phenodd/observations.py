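"""First-flight datasets and their summary statistics.

Raw sightings become first-flight (FF) observations under one of two
contrasting readings of intra-cell scatter:

* **SVA** (spatial variability assumption) — every deduplicated sighting is
  a genuine, spatially variable FF date; all points within a cell are kept.
* **OBA** (observation bias assumption) — intra-cell scatter is reporting
  delay, so only the earliest sighting per grid cell and year is a true FF.

Before either view is taken, sightings are reduced to one per (location,
year): the earliest entry at a given exact (lon, lat) for a given year.

Summary statistics come in three flavours mirroring how point data can be
collapsed: *spatiotemporal* (all observations pooled), *spatial* (per-cell
temporal means), and *temporal* (per-year regional means).  Standard
deviations are sample SDs (n-1 denominator); a single point yields SD 0.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError
from .temperature_io import Cell, GridSpec, Region, SightingRecord, assign_cell

logger = logging.getLogger(__name__)

SVA = "SVA"
OBA = "OBA"


@dataclass(frozen=True)
class FFObservation:
    """One first-flight observation attached to a grid cell."""

    cell: Cell
    year: int
    day_of_year: int
    location: tuple[float, float]  # (lon, lat)

    def __post_init__(self) -> None:
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} out of range")


@dataclass
class FFDataset:
    """First-flight observations for one region under one assumption."""

    assumption: str
    region: str
    observations: list[FFObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.assumption not in (SVA, OBA):
            raise ValueError(f"assumption must be {SVA!r} or {OBA!r}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def years(self) -> list[int]:
        return sorted({o.year for o in self.observations})


@dataclass(frozen=True)
class FFSummaryStats:
    spatiotemporal_mean: float
    spatiotemporal_sd: float
    spatial_mean: float
    spatial_sd: float
    temporal_mean: float
    temporal_sd: float


def dedupe_location_year(records: Sequence[SightingRecord]) -> list[SightingRecord]:
    """Keep only the earliest entry per exact (lon, lat) location and year."""
    best: dict[tuple[float, float, int], SightingRecord] = {}
    for r in records:
        key = (r.lon, r.lat, r.date.year)
        if key not in best or r.date < best[key].date:
            best[key] = r
    # deterministic order: by year, date, then coordinates
    return sorted(best.values(), key=lambda r: (r.date, r.lon, r.lat))


def build_ff_dataset(
    records: Sequence[SightingRecord],
    spec: GridSpec,
    region: Region,
    assumption: str,
) -> FFDataset:
    """Spatially join deduplicated sightings to region cells and apply a view.

    Records mapping to no grid cell, or to a cell outside the region, are
    dropped (counted in a log line).  Under OBA only the earliest observation
    per (cell, year) survives; an exact tie keeps a single representative.
    """
    ds = FFDataset(assumption=assumption, region=region.name)
    dropped = 0
    joined: list[FFObservation] = []
    for r in records:
        cell = assign_cell(r.lon, r.lat, spec)
        if cell is None or cell not in region.cells:
            dropped += 1
            continue
        joined.append(
            FFObservation(
                cell=cell,
                year=r.date.year,
                day_of_year=r.date.timetuple().tm_yday,
                location=(r.lon, r.lat),
            )
        )
    if dropped:
        logger.info(
            "region %s: dropped %d sightings outside the region grid",
            region.name, dropped,
        )
    if assumption == SVA:
        ds.observations = joined
        return ds
    earliest: dict[tuple[Cell, int], FFObservation] = {}
    for obs in sorted(joined, key=lambda o: (o.year, o.day_of_year, o.location)):
        key = (obs.cell, obs.year)
        if key not in earliest:
            earliest[key] = obs
    ds.observations = sorted(
        earliest.values(), key=lambda o: (o.year, o.cell, o.day_of_year)
    )
    return ds


def regional_annual_mean_ff(ds: FFDataset) -> dict[int, float]:
    """Mean observed first-flight day-of-year for each year with data."""
    by_year: dict[int, list[int]] = {}
    for obs in ds.observations:
        by_year.setdefault(obs.year, []).append(obs.day_of_year)
    return {year: statistics.fmean(days) for year, days in sorted(by_year.items())}


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd


def summary_statistics(ds: FFDataset) -> FFSummaryStats:
    """Spatiotemporal / spatial / temporal mean and SD of FF dates.

    * spatiotemporal: over all observations pooled;
    * spatial: over per-cell means of their observations (all years pooled);
    * temporal: over per-year regional means.
    """
    if not ds.observations:
        raise DataError("cannot summarise an empty FF dataset")
    all_days = [o.day_of_year for o in ds.observations]
    by_cell: dict[Cell, list[int]] = {}
    for o in ds.observations:
        by_cell.setdefault(o.cell, []).append(o.day_of_year)
    cell_means = [statistics.fmean(v) for _, v in sorted(by_cell.items())]
    year_means = list(regional_annual_mean_ff(ds).values())

    st_mean, st_sd = _mean_sd(all_days)
    sp_mean, sp_sd = _mean_sd(cell_means)
    tp_mean, tp_sd = _mean_sd(year_means)
    return FFSummaryStats(st_mean, st_sd, sp_mean, sp_sd, tp_mean, tp_sd)


def write_ff_csv(datasets: Iterable[FFDataset], path: str | Path) -> None:
    """CSV with one row per observation across any number of datasets."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["assumption", "region", "cell_lon_index", "cell_lat_index",
             "year", "day_of_year", "lon", "lat"]
        )
        for ds in datasets:
            for o in ds.observations:
                writer.writerow(
                    [ds.assumption, ds.region, o.cell[0], o.cell[1],
                     o.year, o.day_of_year, repr(o.location[0]), repr(o.location[1])]
                )
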