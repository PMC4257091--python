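"""Insect/pathogen disturbance pathways and their scheduling.

Biotic agents are represented functionally by which plant flux they disrupt
rather than by species.  Five pathways are supported:

========  ===========================================  =========
pathway   severity meaning                             kind
========  ===========================================  =========
phloem    fraction of net leaf carbon export removed   press
xylem     fractional reduction in water supply rate    press
leaf      fraction of leaf biomass removed at onset    pulse
root      multiplier (>= 1) on fine-root turnover      press
stem      additive annual per-capita mortality, yr-1   press
========  ===========================================  =========

Press pathways are active from ``start_day`` through ``end_day`` (open-ended
by default); the leaf pathway fires exactly once on its start day.  Multiple
schedules on the same pathway combine multiplicatively on the retained
fraction (phloem, xylem), multiplicatively on the multiplier (root), and
additively (stem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

__all__ = ["PATHWAYS", "PIPSchedule", "Modifiers", "validate_schedule", "active_modifiers"]

PATHWAYS = ("phloem", "xylem", "leaf", "root", "stem")

#: default onset: start of the first growing season for sustained pathways,
#: mid growing season for the one-time defoliation pulse
DEFAULT_PRESS_START = 120
DEFAULT_PULSE_DAY = 180


@dataclass(frozen=True)
class PIPSchedule:
    """One disturbance: pathway identity, severity and timing (simulation days)."""

    pathway: str
    severity: float
    start_day: int
    end_day: Optional[int] = None  # None = persists to the end of the run

    def __post_init__(self) -> None:
        validate_schedule(self)


def validate_schedule(s: PIPSchedule) -> PIPSchedule:
    """Range-check a schedule; error messages name the pathway and bound."""
    if s.pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {s.pathway!r}; expected one of {PATHWAYS}")
    if s.pathway in ("phloem", "xylem", "leaf"):
        if not 0.0 <= s.severity <= 1.0:
            raise ValueError(f"{s.pathway} severity must be a fraction in [0, 1], got {s.severity}")
    elif s.pathway == "root":
        if s.severity < 1.0:
            raise ValueError(f"root severity is a turnover multiplier >= 1, got {s.severity}")
    else:  # stem
        if s.severity < 0.0:
            raise ValueError(f"stem severity is an additive annual rate >= 0, got {s.severity}")
    if s.end_day is not None and s.end_day < s.start_day:
        raise ValueError(f"{s.pathway} schedule ends (day {s.end_day}) before it starts (day {s.start_day})")
    return s


@dataclass(frozen=True)
class Modifiers:
    """Per-day disturbance modifiers applied by the simulator."""

    phloem_tax: float = 0.0
    xylem_loss: float = 0.0
    root_multiplier: float = 1.0
    stem_add: float = 0.0
    defoliation_events: Tuple[float, ...] = ()


NEUTRAL = Modifiers()


def active_modifiers(schedules: Iterable[PIPSchedule], day: int) -> Modifiers:
    """Combine all schedules active on a given simulation day.

    Overlapping schedules are combined, never rejected: retained fractions
    multiply for phloem and xylem, multipliers multiply for root, rates add
    for stem.  Defoliation events are emitted only on their start day.
    """
    phloem_retained = 1.0
    xylem_retained = 1.0
    root_mult = 1.0
    stem_add = 0.0
    events = []
    for s in schedules:
        if s.pathway == "leaf":
            if day == s.start_day:
                events.append(s.severity)
            continue
        end = math.inf if s.end_day is None else s.end_day
        if not s.start_day <= day <= end:
            continue
        if s.pathway == "phloem":
            phloem_retained *= 1.0 - s.severity
        elif s.pathway == "xylem":
            xylem_retained *= 1.0 - s.severity
        elif s.pathway == "root":
            root_mult *= s.severity
        elif s.pathway == "stem":
            stem_add += s.severity
    return Modifiers(
        phloem_tax=1.0 - phloem_retained,
        xylem_loss=1.0 - xylem_retained,
        root_multiplier=root_mult,
        stem_add=stem_add,
        defoliation_events=tuple(events),
    )
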