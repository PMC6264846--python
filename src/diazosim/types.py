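"""Domain types for the chemostat diazotrophy model.

The types are small frozen dataclasses with eager validation; they carry no
behaviour beyond derived convenience properties (supply ratios, molar masses).
All concentrations are mol m-3 (= mM), lengths m, times h.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

from . import constants as C

__all__ = [
    "ElementalFormula",
    "EnergyParameters",
    "StoichiometricMode",
    "CellPhysiology",
    "AmbientEnvironment",
    "CultureConditions",
    "RespirationPolicy",
    "Regime",
    "FluxSolution",
    "ProteinSpecificRates",
    "ThresholdResult",
    "SUCROSE",
    "DEFAULT_BIOMASS",
    "NitrogenSource",
    "default_energy",
    "default_physiology",
]

# Relative atomic masses used for dry-weight conversions.
_ATOMIC_MASS = {"c": 12.011, "h": 1.008, "o": 15.999, "n": 14.007}


class NitrogenSource(str, enum.Enum):
    """Reference state for nitrogen entering or leaving a half-reaction."""

    AMMONIUM = "ammonium"
    N2 = "n2"


@dataclass(frozen=True)
class ElementalFormula:
    """Empirical formula C_c H_h O_o N_n of a compound."""

    c: int
    h: int
    o: int
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "o", "n"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"formula subscript {name}={v!r} must be a non-negative integer")
        if self.c == 0 and self.h == 0 and self.o == 0 and self.n == 0:
            raise ValueError("empty formula")

    @property
    def molar_mass(self) -> float:
        """g mol-1."""
        return sum(getattr(self, k) * m for k, m in _ATOMIC_MASS.items())

    @property
    def n_to_c(self) -> float:
        """Molar N:C ratio (requires carbon)."""
        if self.c == 0:
            raise ValueError("N:C undefined for a carbon-free formula")
        return self.n / self.c

    @property
    def mass_per_carbon(self) -> float:
        """g dry matter per mol carbon (requires carbon)."""
        if self.c == 0:
            raise ValueError("mass per carbon undefined for a carbon-free formula")
        return self.molar_mass / self.c


#: Sucrose, the carbohydrate substrate of the reference chemostat system.
SUCROSE = ElementalFormula(c=12, h=22, o=11)

#: Standard cell empirical formula of the half-reaction framework (N:C = 1:5).
DEFAULT_BIOMASS = ElementalFormula(c=5, h=7, o=2, n=1)


@dataclass(frozen=True)
class EnergyParameters:
    """Energy bookkeeping constants of the stoichiometric network.

    eps_nh4 / eps_n2 are the energy transfer efficiencies for ammonium-based
    and fixation-based growth.  ``atp_per_electron_pair_to_o2`` is the ATP
    yield of respiration per electron pair before efficiency scaling, so the
    usable ATP per electron-equivalent delivered to O2 is
    ``eps * atp_per_electron_pair_to_o2 / 2``.
    """

    eps_nh4: float = C.EPS_NH4
    eps_n2: float = C.EPS_N2
    atp_per_electron_pair_to_o2: float = C.ATP_PER_ELECTRON_PAIR_TO_O2
    atp_per_n2_fixed: float = C.ATP_PER_N2_FIXED
    electrons_per_n2_fixed: float = C.ELECTRONS_PER_N2_FIXED
    atp_per_biomass_c: float = C.ATP_PER_BIOMASS_C

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_nh4 <= 1.0:
            raise ValueError(f"eps_nh4={self.eps_nh4} outside (0, 1]")
        if not 0.0 < self.eps_n2 <= 1.0:
            raise ValueError(f"eps_n2={self.eps_n2} outside (0, 1]")
        if self.eps_n2 > self.eps_nh4:
            raise ValueError("eps_n2 must not exceed eps_nh4")
        if self.atp_per_electron_pair_to_o2 <= 0:
            raise ValueError("atp_per_electron_pair_to_o2 must be > 0")
        if self.atp_per_n2_fixed < 0 or self.electrons_per_n2_fixed < 0:
            raise ValueError("fixation costs must be >= 0")
        if self.atp_per_biomass_c <= 0:
            raise ValueError("atp_per_biomass_c must be > 0")

    def atp_per_electron(self, eps: float) -> float:
        """Usable ATP per electron-equivalent respired at efficiency ``eps``."""
        return eps * self.atp_per_electron_pair_to_o2 / 2.0


@dataclass(frozen=True)
class StoichiometricMode:
    """Per-mol-sucrose ledger of a growth mode with fixation fraction f_n2.

    ``ledger`` itemizes the fate of the 48 electron-equivalents of one mol of
    sucrose: retained in biomass, delivered to O2 (energy generation), or
    consumed by N2 reduction (including the H2 by-product electrons).
    """

    f_n2: float
    yield_biomass_c_per_sucrose: float
    sucrose_per_n_fixed: float
    o2_per_sucrose_respired: float
    ledger: Mapping[str, float]


@dataclass(frozen=True)
class CellPhysiology:
    """Per-cell physiological parameters (geometry, transport, composition)."""

    radius: float = C.CELL_RADIUS
    eps_m: float = C.EPS_M
    diffusivity_o2: float = C.DIFFUSIVITY_O2
    diffusivity_sucrose: float = C.DIFFUSIVITY_SUCROSE
    diffusivity_nh4: float = C.DIFFUSIVITY_NH4
    diffusivity_n2: float = C.DIFFUSIVITY_N2
    carbon_per_cell: float = C.CARBON_PER_CELL
    protein_mass_fraction: float = C.PROTEIN_MASS_FRACTION
    biomass_formula: ElementalFormula = DEFAULT_BIOMASS
    energy: EnergyParameters = field(default_factory=EnergyParameters)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0.0 < self.eps_m <= 1.0:
            raise ValueError(f"eps_m={self.eps_m} outside (0, 1]")
        for name in ("diffusivity_o2", "diffusivity_sucrose", "diffusivity_nh4", "diffusivity_n2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.carbon_per_cell <= 0:
            raise ValueError("carbon_per_cell must be > 0")
        if not 0.0 < self.protein_mass_fraction < 1.0:
            raise ValueError("protein_mass_fraction must be in (0, 1)")
        if self.biomass_formula.c < 1 or self.biomass_formula.n < 1:
            raise ValueError("biomass formula needs carbon and nitrogen")

    def with_(self, **kw) -> "CellPhysiology":
        return replace(self, **kw)


@dataclass(frozen=True)
class AmbientEnvironment:
    """Bulk-medium conditions seen by the cell surface."""

    o2_fraction: float
    o2_saturation: float = C.O2_SATURATION
    n2_concentration: float = C.N2_CONCENTRATION
    temperature_c: float = 30.0  # informational; diffusivities assume 30 degC

    def __post_init__(self) -> None:
        if self.o2_fraction < 0:
            raise ValueError("o2_fraction must be >= 0")
        if self.o2_saturation <= 0:
            raise ValueError("o2_saturation must be > 0")
        if self.n2_concentration < 0:
            raise ValueError("n2_concentration must be >= 0")

    @property
    def o2_concentration(self) -> float:
        """Ambient dissolved O2 (mol m-3)."""
        return self.o2_fraction * self.o2_saturation


@dataclass(frozen=True)
class CultureConditions:
    """Chemostat forcing: dilution rate and inflow composition."""

    sucrose_in: float
    env: AmbientEnvironment
    ammonium_in: float = C.AMMONIUM_IN
    dilution_rate: float = C.DILUTION_RATE

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution_rate must be > 0")
        if self.sucrose_in < 0 or self.ammonium_in < 0:
            raise ValueError("inflow concentrations must be >= 0")

    @property
    def c_over_n(self) -> float:
        """Molar sucrose-to-ammonium supply ratio C/N."""
        if self.ammonium_in == 0:
            return float("inf")
        return self.sucrose_in / self.ammonium_in

    @property
    def c_to_n(self) -> float:
        """Elemental carbon-to-nitrogen supply ratio C:N = 12 C/N."""
        return SUCROSE.c * self.c_over_n

    def with_(self, **kw) -> "CultureConditions":
        return replace(self, **kw)


class RespirationPolicy(str, enum.Enum):
    """Excess-respiration policy.

    SIM1: carbohydrate in excess of energetic demand is respired in every
    regime (constitutive respiratory protection).  SIM2: excess respiration
    occurs only while nitrogen is being fixed.  The two policies yield
    identical biomass and fixation; they differ only in regime-B respiration.
    """

    SIM1 = "sim1"
    SIM2 = "sim2"


class Regime(str, enum.Enum):
    A_CARBON_LIMITED = "A"
    B_AMMONIUM_LIMITED = "B"
    C_MIXED_FIXING = "C"


@dataclass(frozen=True)
class FluxSolution:
    """Steady-state chemostat solution.

    Volumetric rates are mol m-3 h-1; ``carbon_allocation`` itemizes the
    consumed sucrose flux by purpose and sums to ``sucrose_consumed``.
    """

    biomass: float  # mol C m-3
    biomass_gdw: float  # g dry weight m-3
    protein: float  # g m-3
    f_n2: float
    regime: Regime
    sucrose_consumed: float
    nh4_consumed: float
    n_fixed: float
    o2_respired: float
    residual_nh4: float
    residual_sucrose: float
    carbon_allocation: Mapping[str, float]
    policy: RespirationPolicy
    warnings: tuple[str, ...] = ()

    @property
    def washed_out(self) -> bool:
        return self.biomass == 0.0


@dataclass(frozen=True)
class ProteinSpecificRates:
    """Per-protein rates; ``defined`` is False when biomass is zero."""

    defined: bool
    n_fixation_per_protein: float | None = None  # mol N (g protein)-1 h-1
    respiration_per_protein: float | None = None  # mol O2 (g protein)-1 h-1


@dataclass(frozen=True)
class ThresholdResult:
    """Fixation-onset threshold at one oxygen level.

    ``rc_over_n_f`` is the lowest molar sucrose/ammonium supply ratio at which
    nitrogen fixation occurs; ``rc_to_n_f = 12 * rc_over_n_f`` is the same
    threshold as an elemental C:N ratio.
    """

    o2_fraction: float
    rc_over_n_f: float

    @property
    def rc_to_n_f(self) -> float:
        return SUCROSE.c * self.rc_over_n_f


def default_energy() -> EnergyParameters:
    return EnergyParameters()


def default_physiology() -> CellPhysiology:
    return CellPhysiology()
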