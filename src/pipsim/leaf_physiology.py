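"""Leaf-level photosynthesis, stomatal conductance and canopy scaling.

Net assimilation follows the enzyme-kinetic model of C3 photosynthesis: the
gross rate is the minimum of a Rubisco-limited rate ``Ac`` and an electron
transport (RuBP-regeneration) limited rate ``Aj``, with all rate constants
scaled from 25 degC by Arrhenius functions.  Stomatal conductance follows the
optimality-based variant of the Ball-Berry model,

    gs = g0 + 1.6 (1 + g1 / sqrt(D)) A / Ca,

and the two are closed by the CO2 diffusion constraint
``A = (gs/1.6) (Ca - Ci)``, solved per time step for the intercellular CO2
``Ci``.  Leaf temperature is taken equal to air temperature (boundary-layer
conductance assumed negligible) and the canopy is treated as a single big
leaf with Beer-law light absorption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysiologyParams",
    "arrhenius",
    "farquhar_net",
    "dark_respiration",
    "medlyn_gs",
    "couple_leaf",
    "couple_leaf_series",
    "canopy_gpp",
    "maintenance_respiration",
    "LeafSolution",
]

R_GAS = 8.314           # J mol-1 K-1
T_REF_K = 298.15        # 25 degC
P_ATM = 101.325         # kPa, standard atmosphere
PA_PER_PPM = P_ATM * 1e-3  # Pa of partial pressure per ppm at standard pressure
KGC_PER_UMOL = 12.011e-9


@dataclass(frozen=True)
class PhysiologyParams:
    """Leaf biochemistry, conductance and tissue-respiration parameters.

    Rate defaults are literature values for a temperate evergreen conifer;
    kinetic constants and activation energies are the standard tobacco-derived
    set used by most land models.
    """

    vcmax25: float = 45.0       # umol m-2 s-1, max carboxylation at 25 degC
    jmax25: float = 75.15       # umol m-2 s-1, max electron transport (1.67*Vcmax)
    kc25: float = 40.49         # Pa, Michaelis constant for CO2
    ko25: float = 27.84         # kPa, Michaelis constant for O2
    gamma_star25: float = 4.275  # Pa, CO2 compensation point sans Rd
    oi: float = 20.9            # kPa, intercellular O2
    ea_vcmax: float = 65330.0   # J mol-1
    ea_jmax: float = 43540.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    ea_gamma: float = 37830.0
    ea_resp: float = 46390.0
    rd25_frac: float = 0.015    # dark respiration as fraction of vcmax25
    g0: float = 0.01            # mol m-2 s-1, residual conductance
    g1: float = 2.35            # kPa^0.5, stomatal slope
    alpha_q: float = 0.3        # mol e- per mol photon, quantum yield
    theta_j: float = 0.7        # curvature of the light response hyperbola
    k_beer: float = 0.5         # canopy light extinction coefficient
    sla: float = 6.0            # m2 leaf per kgC leaf
    vpd_floor: float = 0.05     # kPa, numerical guard for the 1/sqrt(D) term
    # maintenance respiration, fraction of pool carbon per day at 25 degC
    r_leaf25: float = 0.008
    r_root25: float = 0.002
    r_stem25: float = 0.0005
    sapwood_frac: float = 0.3   # fraction of stem biomass that respires

    def __post_init__(self) -> None:
        if self.g1 <= 0:
            raise ValueError("g1 must be positive")
        if not 0.0 < self.k_beer <= 1.0:
            raise ValueError("k_beer must lie in (0, 1]")


def arrhenius(rate25, ea: float, t_leaf):
    """Scale a rate from 25 degC to ``t_leaf`` with activation energy ``ea``."""
    t_k = np.asarray(t_leaf, dtype=float) + 273.15
    out = rate25 * np.exp(ea * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))
    if np.ndim(t_leaf) == 0 and np.ndim(rate25) == 0:
        return float(out)
    return out


def dark_respiration(t_leaf, p: PhysiologyParams):
    """Leaf dark respiration, umol m-2 s-1."""
    return arrhenius(p.rd25_frac * p.vcmax25, p.ea_resp, t_leaf)


def _j_electron(par, t_leaf, p: PhysiologyParams):
    """Electron transport from the non-rectangular hyperbola (smaller root)."""
    jmax = arrhenius(p.jmax25, p.ea_jmax, t_leaf)
    q = p.alpha_q * np.asarray(par, dtype=float)
    b = q + jmax
    disc = np.sqrt(np.maximum(b * b - 4.0 * p.theta_j * q * jmax, 0.0))
    return (b - disc) / (2.0 * p.theta_j)


def farquhar_net(ci, t_leaf, par, p: PhysiologyParams):
    """Net assimilation (umol m-2 s-1) at intercellular CO2 ``ci`` (Pa).

    Gross assimilation is min(Ac, Aj) clipped at zero; dark respiration is
    then subtracted, so in darkness or at the compensation point the leaf is
    a net source of magnitude Rd.
    """
    ci = np.asarray(ci, dtype=float)
    vcmax = arrhenius(p.vcmax25, p.ea_vcmax, t_leaf)
    kc = arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = arrhenius(p.ko25, p.ea_ko, t_leaf)
    gamma = arrhenius(p.gamma_star25, p.ea_gamma, t_leaf)
    ac = vcmax * (ci - gamma) / (ci + kc * (1.0 + p.oi / ko))
    j = _j_electron(par, t_leaf, p)
    aj = j / 4.0 * (ci - gamma) / (ci + 2.0 * gamma)
    gross = np.maximum(np.minimum(ac, aj), 0.0)
    out = gross - dark_respiration(t_leaf, p)
    if out.ndim == 0:
        return float(out)
    return out


def medlyn_gs(a_net, ca, vpd, p: PhysiologyParams):
    """Stomatal conductance to water vapour, mol m-2 s-1.

    ``ca`` in ppm, ``vpd`` in kPa (floored at ``p.vpd_floor``).  Non-positive
    assimilation returns the residual conductance ``g0``.
    """
    vpd = np.maximum(np.asarray(vpd, dtype=float), p.vpd_floor)
    a_pos = np.maximum(np.asarray(a_net, dtype=float), 0.0)
    out = p.g0 + 1.6 * (1.0 + p.g1 / np.sqrt(vpd)) * a_pos / ca
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LeafSolution:
    """Coupled leaf state: net assimilation, conductance, intercellular CO2."""

    a_net: float   # umol m-2 s-1
    gs: float      # mol m-2 s-1 (H2O)
    ci: float      # Pa


def _diffusion_residual(ci_ppm, t_leaf, par, vpd, ca, p):
    """f(ci) = A_biochem(ci) - A_diffusion(ci); root is the coupled state."""
    a = farquhar_net(np.asarray(ci_ppm) * PA_PER_PPM, t_leaf, par, p)
    gs = medlyn_gs(a, ca, vpd, p)
    return a - gs / 1.6 * (ca - np.asarray(ci_ppm))


def couple_leaf(t_leaf, par, vpd, ca, p: PhysiologyParams) -> LeafSolution:
    """Solve the coupled assimilation-conductance-diffusion system.

    Damped fixed-point iteration on Ci (tolerance well below 0.01 Pa so the
    assimilation residual stays under 1e-3 umol m-2 s-1) with a guaranteed
    bisection fallback on the equivalent scalar root problem.
    """
    rd = dark_respiration(t_leaf, p)
    hi = ca + 1.6 * rd / p.g0 + 50.0  # residual provably positive here
    tol_ppm = 1e-5 / PA_PER_PPM

    ci = 0.7 * ca
    for _ in range(100):
        a = farquhar_net(ci * PA_PER_PPM, t_leaf, par, p)
        gs = medlyn_gs(a, ca, vpd, p)
        ci_new = ca - 1.6 * a / gs
        ci_next = ci + 0.5 * (ci_new - ci)
        if not np.isfinite(ci_next) or ci_next < 0.0 or ci_next > hi:
            break
        if abs(ci_next - ci) < tol_ppm:
            ci = ci_next
            a = farquhar_net(ci * PA_PER_PPM, t_leaf, par, p)
            gs = medlyn_gs(a, ca, vpd, p)
            return LeafSolution(float(a), float(gs), float(ci * PA_PER_PPM))
        ci = ci_next

    # bisection fallback on [0, hi]
    lo, up = 0.0, hi
    for _ in range(60):
        mid = 0.5 * (lo + up)
        if _diffusion_residual(mid, t_leaf, par, vpd, ca, p) < 0.0:
            lo = mid
        else:
            up = mid
    ci = 0.5 * (lo + up)
    a = farquhar_net(ci * PA_PER_PPM, t_leaf, par, p)
    gs = medlyn_gs(a, ca, vpd, p)
    return LeafSolution(float(a), float(gs), float(ci * PA_PER_PPM))


def couple_leaf_series(t_leaf, par, vpd, ca, p: PhysiologyParams, iterations: int = 60):
    """Vectorised coupled solution for whole forcing series.

    Solves the same scalar root problem as :func:`couple_leaf` by bisection
    simultaneously for every time step.  Returns arrays
    ``(a_net, a_gross, gs, ci_pa)``; used by the simulator to precompute the
    leaf response of a recycled forcing year in one pass.
    """
    t_leaf = np.asarray(t_leaf, dtype=float)
    par = np.asarray(par, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    ca = np.broadcast_to(np.asarray(ca, dtype=float), t_leaf.shape)

    rd = dark_respiration(t_leaf, p)
    lo = np.zeros_like(t_leaf)
    hi = ca + 1.6 * rd / p.g0 + 50.0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        neg = _diffusion_residual(mid, t_leaf, par, vpd, ca, p) < 0.0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    ci = 0.5 * (lo + hi)
    a_net = farquhar_net(ci * PA_PER_PPM, t_leaf, par, p)
    gs = medlyn_gs(a_net, ca, vpd, p)
    a_gross = a_net + rd
    return a_net, a_gross, gs, ci * PA_PER_PPM


def canopy_gpp(a_gross_leaf, gs_leaf, lai, p: PhysiologyParams, dt: float = 1800.0):
    """Scale leaf-area fluxes to ground area with a big-leaf Beer-law factor.

    The absorbed-light scaler ``f = (1 - exp(-k LAI)) / k`` multiplies both
    the gross assimilation rate and the stomatal conductance; it tends to LAI
    for sparse canopies and saturates at ``1/k`` for closed ones.  Returns
    ``(gpp, gs_canopy)`` with GPP in kgC per m2 ground per time step of
    ``dt`` seconds.
    """
    if lai < 0:
        raise ValueError("lai must be non-negative")
    scaler = (1.0 - math.exp(-p.k_beer * lai)) / p.k_beer
    gpp = np.maximum(np.asarray(a_gross_leaf, dtype=float), 0.0) * scaler * dt * KGC_PER_UMOL
    gs_canopy = np.asarray(gs_leaf, dtype=float) * scaler
    return gpp, gs_canopy


def maintenance_respiration(b_leaf, b_root, b_stem, t_air, p: PhysiologyParams, dt_days: float = 1.0):
    """Maintenance respiration of the three tissue pools, kgC tree-1.

    Each flux is proportional to its pool (stem: sapwood fraction only) with
    a shared Arrhenius temperature response.  ``t_air`` may be an array, in
    which case the temperature factor is averaged over it (a day of
    half-hourly samples).
    """
    factor = float(np.mean(arrhenius(1.0, p.ea_resp, t_air)))
    r_leaf = p.r_leaf25 * b_leaf * factor * dt_days
    r_root = p.r_root25 * b_root * factor * dt_days
    r_stem = p.r_stem25 * p.sapwood_frac * b_stem * factor * dt_days
    return r_leaf, r_root, r_stem
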