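"""Tree carbon pools: allometry, phloem transport, turnover and allocation.

Each tree in the (single, even-aged) cohort carries four carbon pools —
leaf, fine root, stem and nonstructural storage — plus its diameter at
breast height (DBH).  Stem biomass and the *capacity* of the leaf pool are
power-law functions of DBH; fine-root and storage capacities are fixed
ratios of leaf capacity.  Net canopy carbon (GPP minus leaf respiration)
flows through the phloem into storage, where a phloem-feeding disturbance
can intercept a fraction of it.  Once per day, stored carbon is allocated by
a strict priority ladder:

1. carbon must reach the phloem/storage before it can be spent;
2. maintenance respiration is paid first (by the caller, before allocation);
3. a reserve of K days of maintenance demand is kept in storage;
4. leaf and root pools are restored to a minimum fraction of capacity;
5. storage is refilled to capacity;
6. leaf and root pools are topped up to full capacity;
7. whatever remains is split between stem growth and reproduction.

Growth (any transfer from storage into structural tissue) pays a fractional
growth-respiration cost.  Stem growth feeds back on DBH through the inverse
allometry, raising every capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "TreeState",
    "AllometryParams",
    "Capacities",
    "stem_biomass",
    "dbh_from_stem",
    "capacities",
    "phloem_export",
    "turnover_step",
    "defoliate",
    "allocate",
    "lai_of_stand",
]


@dataclass(frozen=True)
class TreeState:
    """Per-tree carbon pools (kgC) and stem diameter (cm)."""

    dbh: float
    b_leaf: float
    b_root: float
    b_stem: float
    b_store: float

    def __post_init__(self) -> None:
        for name in ("b_leaf", "b_root", "b_stem", "b_store"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        """Total per-tree carbon, kgC."""
        return self.b_leaf + self.b_root + self.b_stem + self.b_store


@dataclass(frozen=True)
class AllometryParams:
    """Allometric coefficients, pool-capacity ratios and allocation rules."""

    stem_a: float = 0.08     # kgC cm^-stem_b, stem biomass coefficient
    stem_b: float = 2.5      # stem biomass exponent
    leaf_a: float = 0.07     # kgC cm^-leaf_b, leaf capacity coefficient
    leaf_b: float = 1.8      # leaf capacity exponent
    q_root: float = 1.0      # root capacity : leaf capacity
    q_store: float = 1.0     # storage capacity : leaf capacity
    f_min: float = 0.5       # priority-restored fraction of leaf/root capacity
    k_days: float = 30.0     # storage reserve, days of maintenance respiration
    f_growth_resp: float = 0.25  # growth respiration fraction of allocation
    f_repro: float = 0.1     # fraction of residual allocation to reproduction
    turnover_leaf: float = 1.0 / 3.0  # yr-1
    turnover_root: float = 0.3        # yr-1
    recruit_mass: float = 250.0       # kgC of reproduction per recruited stem

    def __post_init__(self) -> None:
        for name in ("f_min", "f_growth_resp", "f_repro"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.k_days < 1:
            raise ValueError("k_days must be >= 1")
        if self.stem_b <= 0 or self.leaf_b <= 0:
            raise ValueError("allometric exponents must be positive")


class Capacities(NamedTuple):
    leaf: float
    root: float
    store: float


def stem_biomass(dbh: float, p: AllometryParams) -> float:
    """Stem carbon (kgC) from DBH (cm) via the power-law allometry."""
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    return p.stem_a * dbh ** p.stem_b


def dbh_from_stem(b_stem: float, p: AllometryParams) -> float:
    """Exact inverse of :func:`stem_biomass`."""
    if b_stem <= 0:
        raise ValueError("b_stem must be positive")
    return (b_stem / p.stem_a) ** (1.0 / p.stem_b)


def capacities(dbh: float, p: AllometryParams) -> Capacities:
    """Leaf, root and storage pool capacities (kgC) at a given DBH."""
    leaf_cap = p.leaf_a * dbh ** p.leaf_b
    return Capacities(leaf_cap, p.q_root * leaf_cap, p.q_store * leaf_cap)


class PhloemFlux(NamedTuple):
    to_storage: float    # kgC tree-1, reaches the storage pool (may be < 0)
    intercepted: float   # kgC tree-1, removed by the phloem feeder


def phloem_export(gpp_tree: float, r_leaf: float, phloem_tax: float) -> PhloemFlux:
    """Net leaf carbon export through the phloem, taxed by a phloem feeder.

    Only a positive net gain can be intercepted; a deficit (respiration
    exceeding assimilation) is charged to storage untaxed.
    """
    if not 0.0 <= phloem_tax <= 1.0:
        raise ValueError("phloem_tax must lie in [0, 1]")
    net = gpp_tree - r_leaf
    if net <= 0.0:
        return PhloemFlux(net, 0.0)
    return PhloemFlux(net * (1.0 - phloem_tax), net * phloem_tax)


class TurnoverResult(NamedTuple):
    state: TreeState
    leaf_litter: float
    root_litter: float


def turnover_step(
    state: TreeState, p: AllometryParams, root_multiplier: float = 1.0, dt_days: float = 1.0
) -> TurnoverResult:
    """Baseline leaf and root turnover; a root disturbance multiplies the
    root rate.  Litter carbon is returned for the caller to route to soil."""
    if root_multiplier < 1.0:
        raise ValueError("root_multiplier must be >= 1")
    leaf_litter = state.b_leaf * p.turnover_leaf * dt_days / 365.0
    root_litter = state.b_root * p.turnover_root * root_multiplier * dt_days / 365.0
    leaf_litter = min(leaf_litter, state.b_leaf)
    root_litter = min(root_litter, state.b_root)
    new = replace(
        state, b_leaf=state.b_leaf - leaf_litter, b_root=state.b_root - root_litter
    )
    return TurnoverResult(new, leaf_litter, root_litter)


class DefoliationResult(NamedTuple):
    state: TreeState
    removed_leaf: float


def defoliate(state: TreeState, fraction: float) -> DefoliationResult:
    """Single instantaneous removal of a fraction of leaf biomass."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("defoliation fraction must lie in [0, 1]")
    removed = state.b_leaf * fraction
    return DefoliationResult(replace(state, b_leaf=state.b_leaf * (1.0 - fraction)), removed)


class AllocationResult(NamedTuple):
    state: TreeState
    repro_carbon: float   # kgC tree-1 exported to reproduction
    growth_resp: float    # kgC tree-1 respired while building tissue


def _build(need_leaf: float, need_root: float, budget: float, f_gr: float):
    """Build leaf/root tissue from a carbon budget, pro-rata under scarcity.

    Returns (built_leaf, built_root, spent, growth_resp); spending Δ of
    storage builds Δ(1 - f_gr) of tissue.
    """
    need = need_leaf + need_root
    if need <= 0.0 or budget <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    cost = need / (1.0 - f_gr)
    spent = min(cost, budget)
    frac = spent / cost
    built_leaf = need_leaf * frac
    built_root = need_root * frac
    return built_leaf, built_root, spent, spent - built_leaf - built_root


def allocate(
    state: TreeState, caps: Capacities, maint_daily: float, p: AllometryParams
) -> AllocationResult:
    """One daily pass of the storage-allocation priority ladder.

    ``maint_daily`` is the day's total maintenance respiration demand (which
    the caller has already withdrawn from storage); it sizes the K-day
    reserve that allocation may never dip below.  Every branch conserves
    carbon: the storage drawdown equals built tissue + growth respiration +
    reproduction exactly.
    """
    if maint_daily < 0:
        raise ValueError("maint_daily must be non-negative")
    store = state.b_store
    b_leaf, b_root, b_stem, dbh = state.b_leaf, state.b_root, state.b_stem, state.dbh
    growth_resp = 0.0
    repro = 0.0

    reserve = p.k_days * maint_daily
    if store > reserve:
        # priority 4: restore leaf and root minima, never dipping below reserve
        need_leaf = max(p.f_min * caps.leaf - b_leaf, 0.0)
        need_root = max(p.f_min * caps.root - b_root, 0.0)
        dl, dr, spent, gr = _build(need_leaf, need_root, store - reserve, p.f_growth_resp)
        b_leaf += dl
        b_root += dr
        store -= spent
        growth_resp += gr

    # priority 5: refill storage — only carbon above capacity may proceed
    if store > caps.store:
        # priority 6: top leaf and root up to full capacity
        need_leaf = max(caps.leaf - b_leaf, 0.0)
        need_root = max(caps.root - b_root, 0.0)
        dl, dr, spent, gr = _build(need_leaf, need_root, store - caps.store, p.f_growth_resp)
        b_leaf += dl
        b_root += dr
        store -= spent
        growth_resp += gr

        # priority 7: split the remainder between stem growth and reproduction
        remainder = store - caps.store
        if remainder > 0.0:
            repro = remainder * p.f_repro
            stem_spend = remainder * (1.0 - p.f_repro)
            db_stem = stem_spend * (1.0 - p.f_growth_resp)
            growth_resp += stem_spend * p.f_growth_resp
            b_stem += db_stem
            dbh = dbh_from_stem(b_stem, p)
            store = caps.store

    new = TreeState(dbh=dbh, b_leaf=b_leaf, b_root=b_root, b_stem=b_stem, b_store=store)
    return AllocationResult(new, repro, growth_resp)


def lai_of_stand(b_leaf: float, density: float, sla: float) -> float:
    """Stand leaf area index from per-tree leaf carbon and stem density.

    ``density`` in stems ha-1; the 1e-4 factor converts to per m2.
    """
    if b_leaf < 0 or density < 0 or sla < 0:
        raise ValueError("inputs must be non-negative")
    return b_leaf * sla * density * 1e-4
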