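"""Model-wide defaults, unit conventions and numerical tolerances.

All quantities are SI-derived with the hour as the time unit: mol, m, m3, h.
Concentrations are mol m-3, which is numerically identical to mM, so values
quoted in mM in the chemostat literature can be passed through unchanged.

Every comparison tolerance used by the solvers lives here so that regime
classification, conservation checks and bisection precision are controlled
from a single place.
"""

from __future__ import annotations

# --- numerical tolerances -------------------------------------------------
#: Residual concentration (mol m-3) below which a substrate counts as fully
#: drawn down when classifying regimes.
RESIDUAL_TOL: float = 1e-9

#: Relative tolerance for the carbon / nitrogen / electron conservation
#: identities that every steady state must satisfy.
CONSERVATION_RTOL: float = 1e-9

#: Relative precision of the bisections on sucrose inflow (threshold and
#: f_N2-crossing searches).
BISECTION_RTOL: float = 1e-4

#: Default search bracket for threshold / crossing searches, expressed as the
#: molar sucrose-to-ammonium supply ratio C/N.
CN_BRACKET: tuple[float, float] = (0.01, 200.0)

# --- physical defaults ----------------------------------------------------
#: Oxygen saturation concentration (mol m-3): 100% O2 = 225 uM, approximately
#: air saturation of fresh water at 30 degC.
O2_SATURATION: float = 0.225

#: Dissolved N2 at air equilibrium, 30 degC (mol m-3).
N2_CONCENTRATION: float = 0.45

#: Aqueous diffusion coefficients at 30 degC (m2 h-1), standard-table values.
DIFFUSIVITY_O2: float = 8.4e-6
DIFFUSIVITY_SUCROSE: float = 1.9e-6
DIFFUSIVITY_NH4: float = 7.1e-6
DIFFUSIVITY_N2: float = 7.2e-6

#: Default cell radius (m); an equivalent-sphere radius for a rod-shaped
#: Azotobacter-like cell.
CELL_RADIUS: float = 1.0e-6

#: Carbon quota per cell (mol C cell-1), giving ~1e9 cells mL-1 at the gram
#: per litre biomass densities typical of carbon-replete chemostats.
CARBON_PER_CELL: float = 4.0e-14

#: Protein mass fraction of dry biomass (g protein per g dry weight).
PROTEIN_MASS_FRACTION: float = 0.55

#: Default chemostat dilution rate (h-1), the laboratory operating point.
DILUTION_RATE: float = 0.15

#: Default ammonium inflow concentration (mol m-3).
AMMONIUM_IN: float = 2.5

# --- energy bookkeeping ---------------------------------------------------
#: Energy transfer efficiency for ammonium-based growth (dimensionless).
EPS_NH4: float = 0.54

#: Energy transfer efficiency during fixation-based growth; kept equal to the
#: ammonium value by default (the thresholds cannot distinguish the two, see
#: docs/methods.md on identifiability).
EPS_N2: float = 0.54

#: ATP-equivalents generated per 2 electron-equivalents delivered to O2
#: (classical P/O bookkeeping), before scaling by the transfer efficiency.
ATP_PER_ELECTRON_PAIR_TO_O2: float = 3.0

#: Canonical nitrogenase stoichiometry N2 + 8 e- + 16 ATP -> 2 NH3 + H2.
#: The two electrons leaving as H2 are counted as a fixation cost (not
#: recovered).
ATP_PER_N2_FIXED: float = 16.0
ELECTRONS_PER_N2_FIXED: float = 8.0

#: ATP demand of biomass synthesis per mol biomass carbon, classical maximal
#: Y_ATP bookkeeping (~25 g dw per mol ATP at ~25 g dw per mol biomass C);
#: includes ammonium assimilation.
ATP_PER_BIOMASS_C: float = 1.0

# --- calibrated free parameter -------------------------------------------
#: Dimensionless membrane-layer diffusivity coefficient, one of the two free
#: parameters of the model.  Calibrated (least squares on log residuals,
#: see sweeps.calibrate) against the three oxygen-dependent fixation-onset
#: thresholds RC:Nf = 6.5 / 15 / 100 at 1% / 5% / 60% O2 saturation.
EPS_M: float = 8.5524e-3
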