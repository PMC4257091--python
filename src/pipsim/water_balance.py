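"""Bucket soil hydrology and the supply-demand down-regulation of GPP.

Plant-available soil water is a single store (mm) filled by precipitation and
drained by transpiration, soil evaporation and overflow runoff.  The rate at
which the stand can extract water ("supply") is proportional to soil water
and fine-root biomass; when atmospheric demand (from canopy conductance and
VPD) exceeds supply, GPP and transpiration are both scaled down linearly by
the supply:demand ratio — an isohydric response.  A xylem-disrupting
disturbance acts here as a fractional reduction of the supply rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "SoilWaterState",
    "SoilWaterParams",
    "water_supply",
    "downregulate",
    "transpiration_demand",
    "soil_evaporation",
    "bucket_step",
]

P_ATM = 101.325          # kPa
MM_PER_MOL_H2O = 0.018015  # mm of depth per mol H2O per m2


@dataclass(frozen=True)
class SoilWaterState:
    """Plant-available soil water (mm) in a bucket of fixed capacity."""

    water: float
    capacity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.water <= self.capacity:
            raise ValueError("soil water must lie in [0, capacity]")


@dataclass(frozen=True)
class SoilWaterParams:
    """Bucket size, supply coefficient and soil-evaporation parameters.

    ``k_supply`` sets how much water the root system can deliver per half
    hour per mm of stored water per kgC m-2 of fine roots; its default gives
    a mildly water-limited late summer (daily stress index bottoming out
    around 0.7-0.9) under the default climate and stand.
    """

    capacity: float = 150.0     # mm
    initial_water: float = 120.0  # mm, start-of-run storage (winter-wet)
    k_supply: float = 0.0011    # mm per (mm * kgC m-2) per 30-min step
    e_max: float = 0.03         # mm per 30-min step, wet-soil evaporation cap
    par_ref: float = 800.0      # umol m-2 s-1, radiation saturating evaporation


def water_supply(
    soil: SoilWaterState,
    b_root: float,
    density: float,
    k_supply: float,
    xylem_loss: float = 0.0,
) -> float:
    """Maximum extraction rate, mm per time step.

    Proportional to stored water and to fine-root biomass per ground area;
    a xylem disturbance removes the fraction ``xylem_loss`` of the rate.
    """
    if not 0.0 <= xylem_loss <= 1.0:
        raise ValueError("xylem_loss must lie in [0, 1]")
    root_per_m2 = b_root * density * 1e-4  # kgC m-2
    return k_supply * soil.water * root_per_m2 * (1.0 - xylem_loss)


def downregulate(gpp_pot: float, t_pot: float, supply: float):
    """Linear reduction of GPP and transpiration when supply < demand.

    Returns ``(gpp, transp, stress_index)`` where the stress index is the
    supply:demand ratio (1 = unstressed).
    """
    if t_pot <= supply or t_pot <= 0.0:
        return gpp_pot, t_pot, 1.0
    beta = supply / t_pot
    return gpp_pot * beta, t_pot * beta, beta


def transpiration_demand(
    gs_canopy: float, vpd: float, p_atm: float = P_ATM, dt: float = 1800.0
) -> float:
    """Atmospheric water demand, mm per time step of ``dt`` seconds.

    Molar vapour flux ``gs * D / P`` converted to liquid depth.
    """
    return gs_canopy * (vpd / p_atm) * MM_PER_MOL_H2O * dt


def soil_evaporation(
    soil: SoilWaterState, par: float, e_max: float, par_ref: float
) -> float:
    """Soil surface evaporation, mm per time step.

    Scales with bucket wetness and with radiation (clipped at ``par_ref``);
    zero at night and from a dry bucket.
    """
    if par <= 0.0 or soil.capacity <= 0.0:
        return 0.0
    rad = min(par / par_ref, 1.0)
    return e_max * (soil.water / soil.capacity) * rad


def bucket_step(soil: SoilWaterState, precip: float, transp: float, evap: float):
    """Advance the bucket one step; extraction is capped at available water.

    When requested transpiration plus evaporation exceed the store (including
    the step's rain), both are scaled down proportionally.  Water above
    capacity leaves as runoff.  Returns
    ``(new_state, runoff, transp_actual, evap_actual)`` and closes the water
    balance exactly: ``d(water) = precip - transp - evap - runoff``.
    """
    if precip < 0 or transp < 0 or evap < 0:
        raise ValueError("water fluxes must be non-negative")
    avail = soil.water + precip
    extraction = transp + evap
    if extraction > avail and extraction > 0.0:
        scale = avail / extraction
        transp *= scale
        evap *= scale
    w1 = avail - transp - evap
    if w1 < 0.0:  # guard against rounding
        w1 = 0.0
    runoff = w1 - soil.capacity if w1 > soil.capacity else 0.0
    return replace(soil, water=w1 - runoff), runoff, transp, evap
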