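"""Run configuration: a YAML file mapped onto the package's dataclasses.

An empty file yields the canonical defaults (kinetic constants 0.3/0.8,
domain 15 x 25 with 5 systems run for 500 then 4 x 1000 time units).
Validation is strict and exhaustive: unknown keys and every violated
constraint are reported together, not one at a time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .kinetics import KineticParameters
from .metrics import SectorConfig
from .orchestrator import HorseshoeParams, MaskParams, SimulationSchedule
from .solver import Grid, SolverSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    grid: Grid = Grid()
    solver: SolverSettings = SolverSettings()
    schedule: SimulationSchedule = SimulationSchedule()
    mask_params: MaskParams = MaskParams()
    sector_config: SectorConfig = SectorConfig()

    def to_dict(self) -> dict:
        d = {
            "grid": asdict(self.grid),
            "solver": asdict(self.solver),
            "schedule": {
                "n_systems": self.schedule.n_systems,
                "durations": list(self.schedule.durations),
                "scenario": self.schedule.scenario,
                "seed": self.schedule.seed,
                "amplitude": self.schedule.amplitude,
            },
            "kinetics": _kinetics_to_dict(self.schedule.params),
            "masks": {
                "threshold_fraction": self.mask_params.threshold_fraction,
                "margin": self.mask_params.margin,
                "min_area_cells": self.mask_params.min_area_cells,
                "horseshoe": asdict(self.mask_params.horseshoe),
            },
            "metrics": asdict(self.sector_config),
        }
        return d


def _kinetics_to_dict(params):
    if isinstance(params, KineticParameters):
        return asdict(params)
    return [asdict(p) for p in params]


_SECTION_FIELDS = {
    "grid": {"width_x", "width_y", "n_x", "n_y"},
    "solver": {"dt", "duration", "scheme", "stationarity_tol", "record_every"},
    "schedule": {"n_systems", "durations", "scenario", "seed", "amplitude"},
    "kinetics": {"a", "b", "D_u", "D_v"},
    "masks": {"threshold_fraction", "margin", "min_area_cells", "horseshoe"},
    "horseshoe": {"r_inner", "r_outer", "opening_half_angle", "opening_direction"},
    "metrics": {
        "anterior_half_angle",
        "lateral_bound",
        "posterior_lateral_bound",
        "interbud_radius",
        "interbud_factor",
    },
}


def _check_keys(section: str, data: dict, problems: list[str]) -> dict:
    unknown = set(data) - _SECTION_FIELDS[section]
    if unknown:
        problems.append(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    return {k: v for k, v in data.items() if k in _SECTION_FIELDS[section]}


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    problems: list[str] = []

    known_sections = {"grid", "solver", "schedule", "kinetics", "masks", "metrics"}
    unknown_sections = set(raw) - known_sections
    if unknown_sections:
        problems.append(f"unknown section(s): {', '.join(sorted(unknown_sections))}")

    def build(cls, section: str, **extra):
        data = _check_keys(section, raw.get(section) or {}, problems)
        try:
            return cls(**data, **extra)
        except (TypeError, ValueError) as exc:
            problems.append(f"section '{section}': {exc}")
            return cls(**extra)

    grid = build(Grid, "grid")
    solver = build(SolverSettings, "solver")

    kin_raw = raw.get("kinetics")
    params: KineticParameters | tuple[KineticParameters, ...]
    try:
        if kin_raw is None:
            params = KineticParameters()
        elif isinstance(kin_raw, list):
            params = tuple(
                KineticParameters(**_check_keys("kinetics", d or {}, problems))
                for d in kin_raw
            )
        else:
            params = KineticParameters(**_check_keys("kinetics", kin_raw, problems))
    except (TypeError, ValueError) as exc:
        problems.append(f"section 'kinetics': {exc}")
        params = KineticParameters()

    sched_data = _check_keys("schedule", raw.get("schedule") or {}, problems)
    if "durations" in sched_data:
        sched_data["durations"] = tuple(float(d) for d in sched_data["durations"])
    try:
        schedule = SimulationSchedule(**sched_data, params=params)
    except (TypeError, ValueError) as exc:
        problems.append(f"section 'schedule': {exc}")
        schedule = SimulationSchedule()

    masks_data = _check_keys("masks", raw.get("masks") or {}, problems)
    hs_data = _check_keys("horseshoe", masks_data.pop("horseshoe", None) or {}, problems)
    try:
        horseshoe = HorseshoeParams(**hs_data)
        mask_params = MaskParams(**masks_data, horseshoe=horseshoe)
    except (TypeError, ValueError) as exc:
        problems.append(f"section 'masks': {exc}")
        mask_params = MaskParams()

    sector = build(SectorConfig, "metrics")

    if problems:
        raise ConfigError(problems)
    return RunConfig(grid, solver, schedule, mask_params, sector)


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError([f"top level of {path} must be a mapping"])
    return config_from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
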