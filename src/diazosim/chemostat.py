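"""Steady-state continuous-culture solver with optimal nitrogen sourcing.

At steady state the specific growth rate equals the dilution rate D, supply
fluxes are D times the inflow concentrations, and the limiting substrates are
drawn down to negligible residuals (the zero-net-growth isocline is assumed
small).  Among all feasible fixation fractions f_n2 in [0, 1] the solver
returns the one maximizing the standing biomass concentration.

The optimization reduces to a one-dimensional problem.  Writing costs per mol
of biomass carbon produced: growth metabolism needs ``s_g(f)`` mol sucrose
(linear blend of the pure ammonium / pure fixation modes), and any fixing
cell must respire, in total, exactly the diffusive O2 influx at zero internal
O2 (anoxia for nitrogenase plus the diffusion limit).  The respiratory-
protection top-up makes the total sucrose cost of a fixing state linear in f,
so biomass-from-sucrose X_S(f) decreases while biomass-from-ammonium
X_N(f) = ammonium_in / ((1-f) q) increases, and the optimum sits either at
f = 0, at the crossing of the two curves, or at the oxygen-supply cap on f
(respiration can never exceed the O2 influx, which bounds how much fixation
metabolism a cell can run at low ambient O2).

Three regimes result: (A) carbon-limited growth on ammonium with residual
ammonium, (B) ammonium-limited growth without fixation, and (C) combined
ammonium use and nitrogen fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as C
from .stoichiometry import electron_equivalents, sucrose_per_biomass_c
from .types import (
    SUCROSE,
    CellPhysiology,
    CultureConditions,
    FluxSolution,
    NitrogenSource,
    ProteinSpecificRates,
    Regime,
    RespirationPolicy,
)
from .uptake import o2_influx_at_anoxia, uptake_ceiling

__all__ = [
    "GrowthBudget",
    "InconsistentStateError",
    "solve_steady_state",
    "classify_regime",
    "protein_specific",
]


class InconsistentStateError(RuntimeError):
    """A flux solution violating the regime invariants."""


@dataclass(frozen=True)
class GrowthBudget:
    """Per-biomass-carbon bookkeeping shared by solver, sweeps and tests.

    All quantities are per mol of biomass carbon produced: ``s_a``/``s_b`` are
    the sucrose demands of the pure growth modes, ``phi`` the O2 influx a cell
    receives (at zero internal O2) per mol C it makes at the imposed dilution
    rate, and ``o2_growth(f)`` the O2 consumed by growth metabolism alone.
    """

    q: float  # biomass N:C
    gamma_suc: float  # e- per mol sucrose
    gamma_b: float  # e- per mol biomass C (ammonium reference)
    e_fix_per_n: float  # nitrogenase e- per mol N
    s_a: float
    s_b: float
    phi: float

    @classmethod
    def build(cls, cond: CultureConditions, phys: CellPhysiology) -> "GrowthBudget":
        en = phys.energy
        bf = phys.biomass_formula
        phi = o2_influx_at_anoxia(phys, cond.env) / (cond.dilution_rate * phys.carbon_per_cell)
        return cls(
            q=bf.n_to_c,
            gamma_suc=electron_equivalents(SUCROSE),
            gamma_b=electron_equivalents(bf) / bf.c,
            e_fix_per_n=en.electrons_per_n2_fixed / 2.0,
            s_a=sucrose_per_biomass_c(en, NitrogenSource.AMMONIUM, bf),
            s_b=sucrose_per_biomass_c(en, NitrogenSource.N2, bf),
            phi=phi,
        )

    @property
    def o2_per_sucrose(self) -> float:
        return self.gamma_suc / 4.0

    def s_g(self, f: float) -> float:
        """Sucrose per biomass C for growth metabolism at fixation fraction f."""
        return (1.0 - f) * self.s_a + f * self.s_b

    def o2_growth(self, f: float) -> float:
        """O2 consumed by growth metabolism per biomass C (no protection)."""
        return (self.gamma_suc * self.s_g(f) - self.gamma_b - f * self.q * self.e_fix_per_n) / 4.0

    def fixing_cost(self, f: float) -> float:
        """Total sucrose per biomass C in a fixing state (growth + protection).

        In every fixing state the per-cell respiration equals the O2 influx
        exactly, so the total reduces to (4 phi + gamma_b + f q e_fix) /
        gamma_suc, linear in f.  Only valid for f <= f_o2max.
        """
        return (4.0 * self.phi + self.gamma_b + f * self.q * self.e_fix_per_n) / self.gamma_suc

    @property
    def f_o2max(self) -> float:
        """Largest fixation fraction whose metabolism the O2 influx can oxidize."""
        slope = (self.gamma_suc * (self.s_b - self.s_a) - self.q * self.e_fix_per_n) / 4.0
        if slope <= 0.0:  # fixation adds no net O2 demand; never capped
            return 1.0
        return min(1.0, max(0.0, (self.phi - self.o2_growth(0.0)) / slope))

    def f_crossing(self, c_over_n: float) -> float:
        """f at which ammonium-supported and sucrose-supported biomass agree.

        Solves (1-f) q R = fixing_cost(f) for the supply ratio R; negative
        values mean fixation is not yet beneficial at this R.
        """
        num = self.q * c_over_n * self.gamma_suc - 4.0 * self.phi - self.gamma_b
        den = self.q * c_over_n * self.gamma_suc + self.q * self.e_fix_per_n
        return num / den

    @property
    def viable(self) -> bool:
        """Can non-fixing growth at D be oxidized by the O2 influx at all?"""
        return self.o2_growth(0.0) <= self.phi * (1.0 + 1e-12)


def _washout(cond: CultureConditions, policy: RespirationPolicy, why: str | None) -> FluxSolution:
    warnings = (why,) if why else ()
    return FluxSolution(
        biomass=0.0,
        biomass_gdw=0.0,
        protein=0.0,
        f_n2=0.0,
        regime=Regime.A_CARBON_LIMITED if cond.ammonium_in > C.RESIDUAL_TOL else Regime.B_AMMONIUM_LIMITED,
        sucrose_consumed=0.0,
        nh4_consumed=0.0,
        n_fixed=0.0,
        o2_respired=0.0,
        residual_nh4=cond.ammonium_in,
        residual_sucrose=cond.sucrose_in,
        carbon_allocation={
            "biomass_c": 0.0,
            "synthesis_energy": 0.0,
            "nh4_assimilation_energy": 0.0,
            "fixation_energy": 0.0,
            "respiratory_protection": 0.0,
            "excess_respiration": 0.0,
        },
        policy=policy,
        warnings=warnings,
    )


def solve_steady_state(
    cond: CultureConditions,
    phys: CellPhysiology,
    policy: RespirationPolicy = RespirationPolicy.SIM1,
) -> FluxSolution:
    """Biomass-maximizing steady state of the chemostat.

    The returned biomass and fixation fraction are identical under SIM1 and
    SIM2; the policies differ only in how much of the regime-B carbohydrate
    surplus is respired (SIM1: as much as the O2 influx allows; SIM2: none).
    """
    D = cond.dilution_rate
    S, A = cond.sucrose_in, cond.ammonium_in
    bud = GrowthBudget.build(cond, phys)
    en = phys.energy
    q = bud.q

    if S <= 0.0:
        return _washout(cond, policy, None)
    if not bud.viable:
        return _washout(
            cond,
            policy,
            "washout: diffusive O2 supply cannot oxidize the growth demand at this dilution rate",
        )

    # --- choose the fixation fraction -------------------------------------
    f_star = 0.0
    if A <= 0.0:
        # all nitrogen must come from fixation
        if bud.f_o2max >= 1.0:
            f_star = 1.0
        else:
            return _washout(
                cond, policy, "washout: O2 supply cannot sustain purely diazotrophic growth"
            )
    else:
        f_cross = bud.f_crossing(cond.c_over_n)
        if f_cross > 0.0 and bud.f_o2max > 0.0:
            f_star = min(f_cross, bud.f_o2max)

    excess_respired = 0.0  # volumetric sucrose flux, regime B under SIM1
    if f_star > 0.0:
        # regime C (or pure diazotrophy): ammonium fully drawn down
        if f_star >= 1.0:
            X = S / bud.fixing_cost(1.0)
        else:
            X = A / ((1.0 - f_star) * q)
        cost = bud.fixing_cost(f_star)
        residual_sucrose = max(0.0, S - X * cost)
        residual_nh4 = 0.0
        protection = X * max(0.0, bud.phi - bud.o2_growth(f_star)) / bud.o2_per_sucrose
    else:
        X = min(S / bud.s_a, A / q)
        protection = 0.0
        if S / bud.s_a < A / q:  # regime A: carbon limits, ammonium left over
            residual_sucrose = 0.0
            residual_nh4 = A - q * X
        else:  # regime B: ammonium limits, carbohydrate surplus
            surplus = max(0.0, S - X * bud.s_a)
            residual_nh4 = 0.0
            if policy is RespirationPolicy.SIM1:
                resp_cap = X * max(0.0, bud.phi - bud.o2_growth(0.0)) / bud.o2_per_sucrose / D
                excess_respired = D * min(surplus, resp_cap)
            residual_sucrose = surplus - excess_respired / D

    # --- assemble volumetric fluxes ---------------------------------------
    sucrose_consumed = D * (S - residual_sucrose)
    n_total = q * D * X
    n_fixed = f_star * n_total
    nh4_consumed = n_total - n_fixed
    o2_respired = (
        bud.gamma_suc * sucrose_consumed - bud.gamma_b * D * X - bud.e_fix_per_n * n_fixed
    ) / 4.0

    atp_e_a = en.atp_per_electron(en.eps_nh4)
    atp_e_b = en.atp_per_electron(en.eps_n2)
    alloc = {
        "biomass_c": D * X * bud.gamma_b / bud.gamma_suc,
        "synthesis_energy": D
        * X
        * en.atp_per_biomass_c
        * ((1.0 - f_star) / atp_e_a + f_star / atp_e_b)
        / bud.gamma_suc,
        "nh4_assimilation_energy": 0.0,
        "fixation_energy": D
        * X
        * f_star
        * q
        * (bud.e_fix_per_n + (en.atp_per_n2_fixed / 2.0) / atp_e_b)
        / bud.gamma_suc,
        "respiratory_protection": D * protection,
        "excess_respiration": excess_respired,
    }

    gdw = X * phys.biomass_formula.mass_per_carbon
    sol = FluxSolution(
        biomass=X,
        biomass_gdw=gdw,
        protein=phys.protein_mass_fraction * gdw,
        f_n2=f_star,
        regime=Regime.C_MIXED_FIXING
        if f_star > 0.0
        else (Regime.A_CARBON_LIMITED if residual_nh4 > C.RESIDUAL_TOL else Regime.B_AMMONIUM_LIMITED),
        sucrose_consumed=sucrose_consumed,
        nh4_consumed=nh4_consumed,
        n_fixed=n_fixed,
        o2_respired=o2_respired,
        residual_nh4=residual_nh4,
        residual_sucrose=residual_sucrose,
        carbon_allocation=alloc,
        policy=policy,
        warnings=_uptake_warnings(cond, phys, X, sucrose_consumed, nh4_consumed, n_fixed),
    )
    # defensive: the construction above must satisfy the regime partition
    classify_regime(sol, cond)
    return sol


def _uptake_warnings(
    cond: CultureConditions,
    phys: CellPhysiology,
    X: float,
    sucrose_consumed: float,
    nh4_consumed: float,
    n_fixed: float,
) -> tuple[str, ...]:
    """Verify the complete-drawdown fluxes against the diffusive ceilings.

    Ceilings are evaluated at the inflow (or ambient, for N2) concentration:
    if the per-cell demand exceeds even that, no residual concentration can
    sustain the assumed flux and the solution is flagged.
    """
    if X <= 0.0:
        return ()
    n_cells = X / phys.carbon_per_cell
    checks = [
        ("sucrose", sucrose_consumed / n_cells, cond.sucrose_in),
        ("nh4", nh4_consumed / n_cells, cond.ammonium_in),
        ("n2", (n_fixed / 2.0) / n_cells, None),
    ]
    out = []
    for substrate, demand, c_amb in checks:
        if demand <= 0.0:
            continue
        ceiling = uptake_ceiling(phys, cond.env, substrate, c_amb)
        if demand > ceiling:
            out.append(
                f"per-cell {substrate} demand {demand:.3e} exceeds diffusive ceiling {ceiling:.3e}"
            )
    return tuple(out)


def classify_regime(sol: FluxSolution, cond: CultureConditions) -> Regime:
    """Regime label from the residuals and fixation fraction.

    A: residual ammonium above tolerance, no fixation.  B: ammonium drawn
    down, no fixation.  C: fixation active.  Fixation with residual ammonium
    is an invariant violation.
    """
    if sol.f_n2 > 0.0:
        if sol.residual_nh4 > C.RESIDUAL_TOL:
            raise InconsistentStateError(
                f"fixing (f_n2={sol.f_n2:.4f}) with residual ammonium "
                f"{sol.residual_nh4:.3e} mol m-3"
            )
        return Regime.C_MIXED_FIXING
    return Regime.A_CARBON_LIMITED if sol.residual_nh4 > C.RESIDUAL_TOL else Regime.B_AMMONIUM_LIMITED


def protein_specific(sol: FluxSolution, phys: CellPhysiology) -> ProteinSpecificRates:
    """Volumetric rates divided by the protein concentration.

    Returns an explicitly undefined marker at zero biomass instead of
    propagating NaNs.
    """
    if sol.biomass <= 0.0 or sol.protein <= 0.0:
        return ProteinSpecificRates(defined=False)
    return ProteinSpecificRates(
        defined=True,
        n_fixation_per_protein=sol.n_fixed / sol.protein,
        respiration_per_protein=sol.o2_respired / sol.protein,
    )


def _check_conservation(sol: FluxSolution, cond: CultureConditions, phys: CellPhysiology) -> None:
    """Internal consistency of a solution (used by tests; exact identities)."""
    total_alloc = sum(sol.carbon_allocation.values())
    if not math.isclose(total_alloc, sol.sucrose_consumed, rel_tol=C.CONSERVATION_RTOL, abs_tol=1e-15):
        raise InconsistentStateError("carbon allocation does not sum to sucrose consumed")
    bud = GrowthBudget.build(cond, phys)
    electrons_in = bud.gamma_suc * sol.sucrose_consumed
    electrons_out = (
        bud.gamma_b * cond.dilution_rate * sol.biomass
        + 4.0 * sol.o2_respired
        + bud.e_fix_per_n * sol.n_fixed
    )
    if not math.isclose(electrons_in, electrons_out, rel_tol=C.CONSERVATION_RTOL, abs_tol=1e-15):
        raise InconsistentStateError("electron balance violated")
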