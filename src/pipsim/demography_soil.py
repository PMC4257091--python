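"""Stand demography, soil organic matter and ecosystem-flux accounting.

The stand is a single even-aged cohort with a continuous stem density.
Mortality risk per tree falls off as a negative exponential of the filled
fraction of the storage pool — trees with full nonstructural reserves die at
a low background rate, trees with empty reserves at a high maximum rate —
so carbon starvation produces gradual, delayed death rather than an
instantaneous kill.  A stem-rot disturbance adds directly to the annual
rate.  Dead trees transfer their entire carbon to soil organic matter (SOM),
which also receives turnover litter and respires heterotrophically with a
Q10 temperature sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "StandState",
    "MortalityParams",
    "SoilCarbonParams",
    "mortality_rate",
    "apply_mortality",
    "som_step",
    "nee_accounting",
]


@dataclass(frozen=True)
class StandState:
    """Stand-scale state: stem density (ha-1) and SOM (kgC m-2)."""

    density: float
    som: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.som < 0:
            raise ValueError("som must be non-negative")


@dataclass(frozen=True)
class MortalityParams:
    """Storage-dependent mortality closure.

    The annual per-capita rate is ``m_max * exp(-c * f)`` with ``f`` the
    filled storage fraction and ``c = ln(m_max / m_background)``, so the rate
    is exactly ``m_background`` at full storage and ``m_max`` at empty
    storage.  ``m_max`` is large enough that a stand held at empty storage
    collapses within a few years, which is what severe infestations produce.
    """

    m_background: float = 0.005   # yr-1 at full storage
    m_max: float = 4.5            # yr-1 at empty storage
    stem_pip_add: float = 0.0     # yr-1, additive stem-rot mortality
    dieoff_density: float = 1.0   # stems ha-1, stand die-off threshold

    def __post_init__(self) -> None:
        if self.m_background <= 0:
            raise ValueError("m_background must be positive (rate shape undefined at 0)")
        if self.m_max < self.m_background:
            raise ValueError("m_max must be >= m_background")
        if self.stem_pip_add < 0:
            raise ValueError("stem_pip_add must be non-negative")


@dataclass(frozen=True)
class SoilCarbonParams:
    """First-order SOM decomposition with Q10 temperature sensitivity.

    The default turnover (~1 yr-1) makes the modelled SOM an active litter
    layer whose disturbance anomalies decay over one to a few years; the
    default initial stock puts the control run near input/output equilibrium.
    """

    k_som: float = 1.0    # yr-1, decomposition rate at t_ref
    q10: float = 2.0
    t_ref: float = 10.0   # degC
    som0: float = 0.45    # kgC m-2, initial stock


def mortality_rate(storage_fraction: float, p: MortalityParams) -> float:
    """Annual per-capita mortality at a given filled storage fraction."""
    f = min(max(storage_fraction, 0.0), 1.0)
    c = math.log(p.m_max / p.m_background)
    return p.m_max * math.exp(-c * f) + p.stem_pip_add


class MortalityResult(NamedTuple):
    density: float          # stems ha-1 after the step
    dead_carbon_som: float  # kgC m-2 transferred to SOM


def apply_mortality(
    density: float,
    tree_total_carbon: float,
    m_annual: float,
    dt_days: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> MortalityResult:
    """Reduce stem density by one mortality step.

    Deterministic (expected-value) exponential decline of the continuous
    cohort density by default; pass a seeded ``rng`` for a stochastic mode
    in which the number of deaths is Poisson with the same expectation.
    Whole-tree carbon of the lost stems moves to SOM; per-tree pools are
    untouched.
    """
    if m_annual < 0:
        raise ValueError("m_annual must be non-negative")
    survival = math.exp(-m_annual * dt_days / 365.0)
    if rng is None:
        new_density = density * survival
    else:
        expected_dead = density * (1.0 - survival)
        new_density = max(density - rng.poisson(expected_dead), 0.0)
    dead = density - new_density
    return MortalityResult(new_density, dead * tree_total_carbon * 1e-4)


class SomResult(NamedTuple):
    som: float  # kgC m-2
    rh: float   # kgC m-2 per step, heterotrophic respiration


def som_step(
    som: float,
    litter_in: float,
    t_air: float,
    p: SoilCarbonParams,
    dt_days: float = 1.0,
) -> SomResult:
    """Advance SOM one step: add litter, respire first-order with Q10."""
    if som < 0:
        raise ValueError("som must be non-negative")
    rh = p.k_som * som * p.q10 ** ((t_air - p.t_ref) / 10.0) * dt_days / 365.0
    rh = min(rh, som + litter_in)
    return SomResult(som + litter_in - rh, rh)


class NeeResult(NamedTuple):
    nee: float  # positive = carbon source to the atmosphere
    nep: float  # net ecosystem production, -nee


def nee_accounting(gpp: float, r_auto: float, rh: float) -> NeeResult:
    """Net ecosystem exchange under the micrometeorological sign convention."""
    nee = r_auto + rh - gpp
    return NeeResult(nee, -nee)
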