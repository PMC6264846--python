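"""Shared fixtures and the independent brute-force steady-state oracle.

The oracle re-derives the per-biomass-carbon budget from first principles
(raw formulas and energy constants, Fick's law for the O2 influx) without
touching the solver's internals, evaluates the attainable biomass on a dense
grid of fixation fractions, and returns the grid optimum.  Tests use it both
to cross-check the analytic optimizer and to verify feasibility of returned
states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest

from diazosim import (
    AmbientEnvironment,
    CellPhysiology,
    CultureConditions,
    default_physiology,
)


@pytest.fixture(scope="session")
def phys() -> CellPhysiology:
    return default_physiology()


def make_conditions(
    sucrose: float, ammonium: float = 2.5, o2: float = 0.05, dilution: float = 0.15
) -> CultureConditions:
    return CultureConditions(
        sucrose_in=sucrose,
        ammonium_in=ammonium,
        dilution_rate=dilution,
        env=AmbientEnvironment(o2_fraction=o2),
    )


@dataclass(frozen=True)
class BudgetTerms:
    """Independently derived per-biomass-carbon budget coefficients."""

    q: float
    gamma_suc: float
    gamma_b: float
    s_a: float
    s_b: float
    e_fix_per_n: float
    phi: float  # mol O2 per mol biomass C produced, influx at anoxia


def budget_terms(cond: CultureConditions, physiology: CellPhysiology) -> BudgetTerms:
    en = physiology.energy
    bf = physiology.biomass_formula
    gamma_suc = 4 * 12 + 22 - 2 * 11  # sucrose degree of reduction
    gamma_b = (4 * bf.c + bf.h - 2 * bf.o - 3 * bf.n) / bf.c
    q = bf.n / bf.c
    atp_per_e_a = en.eps_nh4 * en.atp_per_electron_pair_to_o2 / 2
    atp_per_e_b = en.eps_n2 * en.atp_per_electron_pair_to_o2 / 2
    s_a = (gamma_b + en.atp_per_biomass_c / atp_per_e_a) / gamma_suc
    s_b = (
        gamma_b
        + q * en.electrons_per_n2_fixed / 2
        + (en.atp_per_biomass_c + q * en.atp_per_n2_fixed / 2) / atp_per_e_b
    ) / gamma_suc
    influx = (
        4
        * math.pi
        * physiology.radius
        * physiology.diffusivity_o2
        * physiology.eps_m
        * cond.env.o2_concentration
    )
    return BudgetTerms(
        q=q,
        gamma_suc=gamma_suc,
        gamma_b=gamma_b,
        s_a=s_a,
        s_b=s_b,
        e_fix_per_n=en.electrons_per_n2_fixed / 2,
        phi=influx / (cond.dilution_rate * physiology.carbon_per_cell),
    )


def oracle_biomass_at(f: np.ndarray, cond: CultureConditions, physiology: CellPhysiology) -> np.ndarray:
    """Attainable biomass (mol C m-3) at each fixation fraction, or -inf.

    Budget closure per biomass C: growth sucrose s_g(f); a fixing cell's total
    respiration must equal the O2 influx at anoxia (protection top-up v >= 0,
    and metabolism exceeding the influx cannot be oxidized at all); biomass is
    bounded by the sucrose supply and by the ammonium supply.
    """
    f = np.asarray(f, dtype=float)
    t = budget_terms(cond, physiology)
    s_g = (1 - f) * t.s_a + f * t.s_b
    o2_growth = (t.gamma_suc * s_g - t.gamma_b - f * t.q * t.e_fix_per_n) / 4.0
    v = (t.phi - o2_growth) / (t.gamma_suc / 4.0)  # protection sucrose per C
    cost = np.where(f > 0, s_g + np.maximum(v, 0.0), s_g)

    x_sucrose = np.where(cost > 0, cond.sucrose_in / cost, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_ammonium = np.where(f < 1.0, cond.ammonium_in / ((1.0 - f) * t.q), np.inf)
    x = np.minimum(x_sucrose, x_ammonium)

    # infeasible states: fixing metabolism the O2 influx cannot oxidize,
    # growth without fixation likewise, or no nitrogen at all
    infeasible = (o2_growth > t.phi * (1 + 1e-12)) | ((f < 1.0) & (cond.ammonium_in == 0) & (f > 0))
    if cond.ammonium_in == 0:
        infeasible = infeasible | (f < 1.0)
    return np.where(infeasible, -np.inf, x)


def oracle_best(
    cond: CultureConditions, physiology: CellPhysiology, n_grid: int = 2001
) -> tuple[float, float]:
    """(f_best, biomass_best) over a dense fixation-fraction grid.

    Ties are broken toward the lower f (cheaper nitrogen); an all-infeasible
    grid is washout (0, 0).
    """
    f = np.linspace(0.0, 1.0, n_grid)
    x = oracle_biomass_at(f, cond, physiology)
    i = int(np.argmax(x))  # argmax returns the first (lowest-f) maximizer
    if not np.isfinite(x[i]) or x[i] <= 0.0:
        return 0.0, 0.0
    return float(f[i]), float(x[i])
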