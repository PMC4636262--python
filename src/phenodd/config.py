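"""Run configuration: one YAML file validated before any computation.

CLI flags override file values.  Unknown top-level keys are rejected so a
typo fails fast rather than silently falling back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_KNOWN_KEYS = {
    "seed", "species", "data_dir", "dd_c_true", "t0_true",
    "sighting_years", "climate_years", "t0_scan", "ddc_step",
    "assumptions", "observer", "regions", "periods", "model",
    "warming_per_period",
}


@dataclass
class RunConfig:
    seed: int = 0
    species: str = "Anthocharis cardamines"
    data_dir: str | None = None
    dd_c_true: float = 160.0
    t0_true: float = 5.5
    sighting_years: tuple[int, int] = (2003, 2010)
    climate_years: tuple[int, int] = (2003, 2010)
    t0_scan: dict = field(default_factory=lambda: {"min": 0.0, "max": 10.0, "step": 0.5})
    ddc_step: float = 1.0
    assumptions: tuple[str, ...] = ("sva", "oba")
    observer: dict = field(default_factory=dict)
    regions: dict | None = None  # name -> ClimateScenario overrides; None = packaged demo
    periods: list[dict] = field(default_factory=list)
    model: dict | None = None  # explicit {dd_c, t0} bypasses calibration
    warming_per_period: float = 0.0

    def validate(self) -> None:
        a, b = self.sighting_years
        c, d = self.climate_years
        if a > b or c > d:
            raise ConfigError("year ranges must be ascending")
        if not (c <= a and b <= d):
            raise ConfigError("sighting_years must lie within climate_years")
        scan = self.t0_scan
        if scan["step"] <= 0 or scan["min"] > scan["max"]:
            raise ConfigError("invalid t0_scan block")
        if self.ddc_step <= 0:
            raise ConfigError("ddc_step must be positive")
        for case in self.assumptions:
            if case not in ("sva", "oba"):
                raise ConfigError(f"unknown assumption {case!r}")
        if self.model is not None:
            if not {"dd_c", "t0"} <= set(self.model):
                raise ConfigError("model block needs dd_c and t0")
        for p in self.periods:
            if not {"name", "start", "end"} <= set(p):
                raise ConfigError("each period needs name, start, end")
            if p["start"] > p["end"]:
                raise ConfigError(f"period {p['name']!r}: start > end")

    def echo(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path | None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load YAML config (optional) and apply non-None CLI overrides."""
    raw: dict[str, Any] = {}
    if path is not None:
        try:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key, value in raw.items():
        if key in ("sighting_years", "climate_years", "assumptions"):
            value = tuple(value)
        if key == "t0_scan":
            value = {**cfg.t0_scan, **value}
        setattr(cfg, key, value)
    if overrides:
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
    cfg.validate()
    return cfg
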