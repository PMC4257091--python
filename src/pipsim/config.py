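"""Hierarchical run configuration: defaults, YAML I/O and hashing.

All tunable parameters of the model live in the dataclasses of the process
modules; :class:`SimConfig` composes them into one tree mirrored by the YAML
layout.  A YAML file only needs the entries that differ from the defaults.

Example::

    years: 4
    climate:
      mean_annual_temp: 7.3
      annual_precip: 550
    stand:
      dbh0: 10.0
      density0: 700
    pips:
      - {pathway: xylem, severity: 0.5, start_day: 120}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import List

import yaml

from .carbon_economy import AllometryParams
from .demography_soil import MortalityParams, SoilCarbonParams
from .disturbance import DEFAULT_PRESS_START, DEFAULT_PULSE_DAY, PIPSchedule
from .leaf_physiology import PhysiologyParams
from .met_forcing import ClimateTarget
from .water_balance import SoilWaterParams

__all__ = ["StandInit", "SimConfig", "default_config", "load_config", "save_config", "config_hash", "with_pip"]


@dataclass(frozen=True)
class StandInit:
    """Initial stand: even-aged cohort at a single DBH and density."""

    dbh0: float = 10.0       # cm
    density0: float = 700.0  # stems ha-1


@dataclass(frozen=True)
class SimConfig:
    years: int = 4
    seed: int = 42
    stochastic_mortality: bool = False
    climate: ClimateTarget = field(default_factory=ClimateTarget)
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    soil_water: SoilWaterParams = field(default_factory=SoilWaterParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    soil_carbon: SoilCarbonParams = field(default_factory=SoilCarbonParams)
    stand: StandInit = field(default_factory=StandInit)
    pips: List[PIPSchedule] = field(default_factory=list)


def default_config(**overrides) -> SimConfig:
    """The frozen default parameterisation (optionally with replacements)."""
    return dataclasses.replace(SimConfig(), **overrides) if overrides else SimConfig()


_SECTIONS = {
    "climate": ClimateTarget,
    "physiology": PhysiologyParams,
    "soil_water": SoilWaterParams,
    "allometry": AllometryParams,
    "mortality": MortalityParams,
    "soil_carbon": SoilCarbonParams,
    "stand": StandInit,
}


def config_from_dict(data: dict) -> SimConfig:
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**value)
        elif key == "pips":
            kwargs[key] = [PIPSchedule(**entry) for entry in value]
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> SimConfig:
    """Load a YAML config; missing entries fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: SimConfig) -> str:
    """Stable short hash identifying a full parameterisation."""
    canon = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def with_pip(cfg: SimConfig, pathway: str, severity: float, start_day: int | None = None,
             end_day: int | None = None) -> SimConfig:
    """Return a copy of ``cfg`` with one disturbance added.

    Sustained pathways default to onset at the start of the first growing
    season (day 120) persisting to the end of the run; the defoliation pulse
    defaults to a single event on day 180.
    """
    if start_day is None:
        start_day = DEFAULT_PULSE_DAY if pathway == "leaf" else DEFAULT_PRESS_START
    sched = PIPSchedule(pathway=pathway, severity=severity, start_day=start_day, end_day=end_day)
    return dataclasses.replace(cfg, pips=list(cfg.pips) + [sched])
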