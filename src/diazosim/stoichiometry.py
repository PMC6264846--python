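"""Half-reaction bookkeeping: electron equivalents, yields and fixation costs.

The growth stoichiometry is the balanced-half-reaction framework of microbial
energetics: the electron-equivalents of the donor (sucrose, 48 e- per mol) are
split between synthesis (electrons retained in biomass), nitrogen reduction
(when fixing), and respiration (electrons delivered to O2).  Respiration
generates ATP at ``eps * atp_per_electron_pair_to_o2 / 2`` per electron, and
the split is fixed by requiring that the ATP generated exactly covers the ATP
demand of synthesis plus, when fixing, the nitrogenase ATP demand.

Degree-of-reduction convention: gamma = 4c + h - 2o - k*n with k = 3 when
nitrogen enters or leaves the reaction as NH3/NH4+ (nitrogen at oxidation
state -3 carries no transferable electrons relative to the ammonium
reference) and k = 0 when the reference is N2.  Hence sucrose -> 48,
C5H7O2N -> 20 (ammonium reference) or 23 (N2 reference).
"""

from __future__ import annotations

from .types import (
    DEFAULT_BIOMASS,
    SUCROSE,
    ElementalFormula,
    EnergyParameters,
    NitrogenSource,
    StoichiometricMode,
)

__all__ = [
    "MalformedFormulaError",
    "InfeasibleEnergyBalanceError",
    "electron_equivalents",
    "synthesis_yield",
    "sucrose_per_biomass_c",
    "fixation_overhead",
    "mode_for",
]


class MalformedFormulaError(ValueError):
    """A carbon compound with a negative degree of reduction."""


class InfeasibleEnergyBalanceError(ValueError):
    """Energy closure would require more carbon than the donor provides."""


def electron_equivalents(
    formula: ElementalFormula,
    n_reference: NitrogenSource = NitrogenSource.AMMONIUM,
) -> float:
    """Electron-equivalents per mol transferable to O2 on full oxidation.

    For carbon compounds this is the degree of reduction (a donor quantity;
    negative values indicate a malformed formula).  Carbon-free species may be
    net acceptors, for which the magnitude is returned: O2 accepts 4 e- per
    mol, water is redox-neutral.
    """
    k = 3 if n_reference is NitrogenSource.AMMONIUM else 0
    gamma = 4 * formula.c + formula.h - 2 * formula.o - k * formula.n
    if formula.c > 0:
        if gamma < 0:
            raise MalformedFormulaError(
                f"degree of reduction {gamma} < 0 for carbon compound {formula}"
            )
        return float(gamma)
    return float(abs(gamma))


def sucrose_per_biomass_c(
    params: EnergyParameters,
    n_source: NitrogenSource,
    biomass: ElementalFormula = DEFAULT_BIOMASS,
) -> float:
    """Mol sucrose consumed per mol biomass carbon for a pure nitrogen source.

    Sums, in electron-equivalents per biomass C: electrons retained in
    biomass, electrons consumed by nitrogenase (N2 source only), and
    electrons respired to O2 to generate the required ATP.
    """
    gamma_suc = electron_equivalents(SUCROSE)
    gamma_b = electron_equivalents(biomass) / biomass.c  # e- per biomass C
    q = biomass.n_to_c

    atp_demand = params.atp_per_biomass_c
    e_nitrogenase = 0.0
    if n_source is NitrogenSource.N2:
        # per N: half the per-N2 cost
        e_nitrogenase = q * params.electrons_per_n2_fixed / 2.0
        atp_demand += q * params.atp_per_n2_fixed / 2.0
        eps = params.eps_n2
    else:
        eps = params.eps_nh4

    e_to_o2 = atp_demand / params.atp_per_electron(eps)
    s = (gamma_b + e_nitrogenase + e_to_o2) / gamma_suc
    # Energy closure must not demand less sucrose than the carbon skeletons
    # require; below that the electron split has no feasible solution.
    if s < 1.0 / SUCROSE.c:
        raise InfeasibleEnergyBalanceError(
            f"energy closure yields {1.0 / s:.3f} mol biomass C per sucrose, "
            f"exceeding the {SUCROSE.c} C the donor provides"
        )
    return s


def synthesis_yield(
    params: EnergyParameters,
    n_source: NitrogenSource,
    biomass: ElementalFormula = DEFAULT_BIOMASS,
) -> float:
    """Mol biomass carbon produced per mol sucrose consumed (growth + growth energy)."""
    return 1.0 / sucrose_per_biomass_c(params, n_source, biomass)


def fixation_overhead(params: EnergyParameters) -> float:
    """Mol sucrose additionally oxidized per mol N fixed, relative to ammonium.

    Combines the nitrogenase electron demand (``electrons_per_n2_fixed / 2``
    per N) with the electrons respired to service its ATP demand
    (``atp_per_n2_fixed / 2`` per N) at the fixation-mode efficiency.
    """
    e_direct = params.electrons_per_n2_fixed / 2.0
    e_energy = (params.atp_per_n2_fixed / 2.0) / params.atp_per_electron(params.eps_n2)
    return (e_direct + e_energy) / electron_equivalents(SUCROSE)


def mode_for(
    f_n2: float,
    params: EnergyParameters,
    biomass: ElementalFormula = DEFAULT_BIOMASS,
) -> StoichiometricMode:
    """Blended growth mode with a fraction ``f_n2`` of nitrogen from fixation.

    The blend is linear on a per-nitrogen basis between the two pure modes
    (which, at fixed biomass N:C, is also linear per biomass carbon), so the
    sucrose demand per biomass C interpolates linearly and the yield is its
    reciprocal.  The electron ledger is itemized per mol sucrose and closes
    exactly on the 48 electron-equivalents of sucrose.
    """
    if not 0.0 <= f_n2 <= 1.0:
        raise ValueError(f"f_n2={f_n2} outside [0, 1]")
    gamma_suc = electron_equivalents(SUCROSE)
    gamma_b = electron_equivalents(biomass) / biomass.c
    q = biomass.n_to_c

    s_a = sucrose_per_biomass_c(params, NitrogenSource.AMMONIUM, biomass)
    s_b = sucrose_per_biomass_c(params, NitrogenSource.N2, biomass)
    s = (1.0 - f_n2) * s_a + f_n2 * s_b
    y = 1.0 / s  # mol biomass C per mol sucrose

    e_biomass = gamma_b * y
    e_n2 = f_n2 * q * y * params.electrons_per_n2_fixed / 2.0
    e_o2 = gamma_suc - e_biomass - e_n2
    return StoichiometricMode(
        f_n2=f_n2,
        yield_biomass_c_per_sucrose=y,
        sucrose_per_n_fixed=fixation_overhead(params),
        o2_per_sucrose_respired=gamma_suc / 4.0,
        ledger={
            "to_biomass": e_biomass,
            "to_o2": e_o2,
            "to_n2_reduction": e_n2,
        },
    )
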