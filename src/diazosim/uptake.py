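"""Diffusion-limited exchange between the medium and a spherical cell.

Fick's law for a sphere in an unstirred medium gives a per-cell flux of
``4 pi r D (c_ambient - c_internal)``; the dimensionless membrane-layer
coefficient ``eps_m`` scales the bulk-water result identically for every
species.  The same expression, evaluated for O2 at zero internal
concentration, sets the oxygen-scavenging demand that gates nitrogen
fixation: nitrogenase requires a nearly anoxic cytosol, so a fixing cell must
respire at least the entire diffusive O2 influx.
"""

from __future__ import annotations

import math

from .stoichiometry import electron_equivalents
from .types import SUCROSE, AmbientEnvironment, CellPhysiology

__all__ = [
    "diffusive_flux",
    "o2_influx_at_anoxia",
    "o2_scavenging_demand",
    "uptake_ceiling",
    "SUBSTRATE_DIFFUSIVITIES",
]

#: Map substrate name -> CellPhysiology diffusivity attribute.
SUBSTRATE_DIFFUSIVITIES = {
    "sucrose": "diffusivity_sucrose",
    "nh4": "diffusivity_nh4",
    "n2": "diffusivity_n2",
    "o2": "diffusivity_o2",
}


def diffusive_flux(
    phys: CellPhysiology,
    diffusivity: float,
    c_ambient: float,
    c_internal: float,
) -> float:
    """Per-cell diffusive flux (mol cell-1 h-1), positive into the cell."""
    if c_ambient < 0 or c_internal < 0:
        raise ValueError("concentrations must be >= 0")
    return 4.0 * math.pi * phys.radius * diffusivity * phys.eps_m * (c_ambient - c_internal)


def o2_influx_at_anoxia(phys: CellPhysiology, env: AmbientEnvironment) -> float:
    """Diffusive O2 influx (mol O2 cell-1 h-1) at zero internal O2.

    This is both the maximum O2 a cell can respire and the amount it *must*
    respire to keep the cytosol anoxic while fixing nitrogen.
    """
    return diffusive_flux(phys, phys.diffusivity_o2, env.o2_concentration, 0.0)


def o2_scavenging_demand(phys: CellPhysiology, env: AmbientEnvironment) -> float:
    """Sucrose oxidation rate (mol sucrose cell-1 h-1) that balances the O2 influx.

    Complete oxidation of sucrose consumes 12 mol O2 per mol (48 electron
    equivalents at 4 per O2), so the demand is the anoxic O2 influx / 12.
    """
    o2_per_sucrose = electron_equivalents(SUCROSE) / 4.0
    return o2_influx_at_anoxia(phys, env) / o2_per_sucrose


def uptake_ceiling(
    phys: CellPhysiology,
    env: AmbientEnvironment,
    substrate: str,
    c_ambient: float | None = None,
) -> float:
    """Maximum per-cell uptake (mol cell-1 h-1): diffusive flux at zero internal.

    For n2 and o2 the ambient concentration defaults to the environment value;
    for sucrose and nh4 it must be supplied (the chemostat solver uses it to
    verify that the complete-consumption fluxes it assumes are attainable).
    """
    try:
        attr = SUBSTRATE_DIFFUSIVITIES[substrate]
    except KeyError:
        raise ValueError(f"unknown substrate {substrate!r}") from None
    if c_ambient is None:
        if substrate == "n2":
            c_ambient = env.n2_concentration
        elif substrate == "o2":
            c_ambient = env.o2_concentration
        else:
            raise ValueError(f"c_ambient required for substrate {substrate!r}")
    return diffusive_flux(phys, getattr(phys, attr), c_ambient, 0.0)
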