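# Methods

`diazosim` simulates a heterotrophic, nitrogen-fixing bacterium (an
*Azotobacter vinelandii*-like cell) growing in continuous culture on sucrose
plus ammonium, with diffusion-limited gas exchange and respiratory protection
of nitrogenase. This note documents the model, its assumptions, the default
parameterization and its calibration, the numerical choices, and the known
limitations.

## Model

### Stoichiometric closure

Cellular metabolism is a coarse-grained flux-balance network built from
balanced half-reactions, conserving mass, electrons and energy. The currency
is the electron-equivalent: the degree of reduction γ = 4c + h − 2o − kn of a
compound C_cH_hO_oN_n, with k = 3 when nitrogen enters or leaves as
NH₃/NH₄⁺ and k = 0 against the N₂ reference. Sucrose carries γ_S = 48 e⁻
mol⁻¹; the default biomass formula C₅H₇O₂N carries 20 e⁻ mol⁻¹ (4 per
carbon) with the ammonium reference.

Donor electrons split three ways: retained in biomass, consumed by
nitrogenase, or respired to O₂. Respiration of one electron-equivalent
yields ε·P/2 ATP, where P is the ATP yield per electron pair
(`atp_per_electron_pair_to_o2`, default 3 — classical P/O bookkeeping) and ε
the energy transfer efficiency. The split is closed by requiring the ATP
generated to cover exactly the ATP demand:

* synthesis: `atp_per_biomass_c` = 1 ATP per mol biomass C (classical
  maximal Y_ATP ≈ 25 g dw per mol ATP at ≈ 25 g dw per mol biomass C,
  ammonium assimilation included);
* nitrogenase, when fixing: N₂ + 8 e⁻ + 16 ATP → 2 NH₃ + H₂. The two
  electrons leaving as H₂ are counted as a fixation cost and not recovered.

This gives, per mol of biomass carbon, the sucrose demand of the two pure
growth modes,

    s_A = (γ_B/c + a/(ε_NH4 P/2)) / γ_S                    (ammonium)
    s_B = (γ_B/c + q·4 + (a + 8q)/(ε_N2 P/2)) / γ_S        (fixation)

with q = N:C = 0.2 and a = `atp_per_biomass_c`. With the defaults
(ε_NH4 = ε_N2 = 0.54) the yields are Y_A = 1/s_A ≈ 9.17 and
Y_B ≈ 5.99 mol biomass C per mol sucrose; fixation-based growth is always
costlier. A mixed mode with fixation fraction f_N2 is the linear per-nitrogen
blend of the pure modes, so s_g(f) interpolates linearly and the yield is its
reciprocal.

ε = 0.54 for ammonium-based growth is taken as given (a value constrained by
compiled chemostat growth-efficiency data for microbes on sugar plus
ammonium); ε and P and a are jointly degenerate — only ε·P/a enters the
yields — so a and P are fixed at their classical bookkeeping values and all
remaining freedom is carried by the two free parameters discussed below.

### Diffusive exchange and respiratory protection

The cell is a sphere of radius r = 1 µm exchanging solutes with the medium by
molecular diffusion; the per-cell flux is 4πr·D·ε_m·(c_out − c_in), where
ε_m ∈ (0, 1] is a single dimensionless membrane-layer coefficient applied
identically to all species. Nitrogenase requires a nearly anoxic cytosol, so
a fixing cell must draw internal O₂ to ≈ 0, which makes its total
respiration exactly equal to the diffusive O₂ influx at zero internal O₂
(Fick flux at full gradient): respiration beyond the energetic demand —
respiratory protection — makes up any deficit by oxidizing extra sucrose
(12 O₂ per sucrose).

The same influx is also a *ceiling*: a cell cannot respire more O₂ than
diffuses in. Two consequences that the budget makes explicit:

* at low ambient O₂ the fixation fraction is capped by the available
  oxidant (fixation metabolism is strongly oxidative), so fixation rates
  saturate at high C/N;
* below an O₂ floor (≈ 0.9% of saturation with the shipped defaults at
  D = 0.15 h⁻¹) even non-fixing growth cannot be oxidized at the imposed
  rate and the culture washes out. Just above the floor, growth respiration
  alone depletes internal O₂ and respiratory protection is unnecessary —
  the regime the model predicts around 1% O₂ saturation.

### Chemostat steady state and optimization

At dilution rate D the specific growth rate equals D, supply fluxes are
D·(inflow), and limiting substrates are drawn down to negligible residuals
(the zero-net-growth isocline is assumed small relative to the inflows; no
Monod kinetics). Writing X for the biomass concentration (mol C m⁻³), the
per-biomass-carbon budget makes the attainable biomass at fixation fraction f

    X(f) = min(  S_in / [s_g(f) + v(f)] ,   A_in / ((1−f) q)  )

where v(f) ≥ 0 is the respiratory-protection sucrose and the O₂-influx
identity makes s_g + v = (4φ + γ_B/c + 4qf)/γ_S linear in f (φ is the O₂
influx per mol biomass C produced, = per-cell influx / (D·carbon_per_cell)).
The model selects the f that maximizes X. Because the sucrose-supported
branch decreases and the ammonium-supported branch increases in f, the
optimum is f = 0, the crossing of the two branches (solved in closed form),
or the oxidant cap on f — whichever is smallest. A 2001-point brute-force
grid over f, written independently of the solver, is retained as a test
oracle, and every returned state is checked against the carbon, nitrogen and
electron conservation identities at 1e-9 relative tolerance.

Three regimes result, classified from the residuals: **A** carbon-limited
growth on ammonium (residual ammonium > 0), **B** ammonium-limited growth
without fixation, **C** combined ammonium use and fixation. Biomass rises
with sucrose inflow in A, is constant across B (ammonium fixes it), and
rises again in C.

Two respiration policies bracket the behaviour of regime B: **sim1**
respires all surplus carbohydrate constitutively (up to the O₂-influx
ceiling); **sim2** respires surplus only while fixing, leaving it as
residual sucrose otherwise. Biomass, fixation and regime structure are
identical under both; only regime-B respiration differs (sim1 ≥ sim2).

## Free parameters and calibration

The two free parameters are ε_m (membrane-layer diffusivity coefficient) and
ε_N2 (fixation-mode transfer efficiency). The fixation-onset threshold —
the lowest supply ratio R_C/N = sucrose/ammonium at which fixation occurs,
reported also as the elemental ratio R_C:N = 12·R_C/N — follows the closed
form R_C:N = (4φ + γ_B/c)/(4q), increasing linearly with ambient O₂ through
φ ∝ ε_m·[O₂].

`sweeps.calibrate` fits the free parameters by least squares on log-threshold
residuals against the model's three reference threshold predictions
(R_C:N = 6.5 at 1%, 15 at 5%, 100 at 60% of O₂ saturation, at D = 0.15 h⁻¹
and 2.5 mol m⁻³ ammonium). The thresholds are provably insensitive to ε_N2
(in any fixing state the protection top-up absorbs changes in fixation-mode
growth respiration), so ε_N2 is pinned at ε_NH4 = 0.54 and the fitter warns
about identifiability if asked to vary it. The fit over ε_m is stable from
any starting point and gives the shipped default **ε_m = 8.5524 × 10⁻³**,
with fitted thresholds 6.69 / 13.46 / 106.6 (+3%, −10%, +7%). A holdout
protocol (fitting the 1% threshold only) predicts the 5% and 60% thresholds
within a factor of two, the identifiability check exercised in the test
suite.

A structural note: whenever O₂ scavenging dominates the fixation budget, the
supply ratio at which f_N2 reaches ½ obeys the identity
crossing(C/N) = R_C:N(same O₂)/6 + 1/12 — about twice the onset ratio —
because doubling the biomass supported per unit ammonium doubles the
(per-biomass-constant) scavenging bill. At 60% O₂ the calibrated model puts
this crossing at C/N ≈ 17.8.

## Default parameters

| parameter | default | unit | basis |
|---|---|---|---|
| dilution rate D | 0.15 | h⁻¹ | reference chemostat operating point |
| ammonium inflow | 2.5 | mol m⁻³ | reference medium |
| sucrose inflow | 0–37.5 | mol m⁻³ | C/N 0–15 at 2.5 mM ammonium |
| O₂ saturation | 0.225 | mol m⁻³ | 100% = 225 µM at 30 °C |
| dissolved N₂ | 0.45 | mol m⁻³ | air equilibrium, 30 °C |
| cell radius | 1.0 × 10⁻⁶ | m | equivalent sphere |
| carbon per cell | 4 × 10⁻¹⁴ | mol C | ~10⁹ cells mL⁻¹ at g L⁻¹ densities |
| protein mass fraction | 0.55 | g g⁻¹ dw | typical bacterial composition |
| D_O₂ / D_NH₄ / D_N₂ / D_sucrose | 8.4 / 7.1 / 7.2 / 1.9 × 10⁻⁶ | m² h⁻¹ | aqueous tables, 30 °C |
| ε_NH4 = ε_N2 | 0.54 | – | fixed (see above) |
| ε_m | 8.5524 × 10⁻³ | – | calibrated (see above) |
| P (ATP / e⁻ pair) | 3 | – | classical P/O |
| a (ATP / biomass C) | 1 | – | maximal Y_ATP bookkeeping |
| nitrogenase | 8 e⁻, 16 ATP per N₂ | – | canonical reaction, H₂ lost |

Biomass N:C (0.2 via C₅H₇O₂N) and all of the above are configurable through
the YAML config (`diazosim --config`).

## Numerical choices

* All searches are deterministic; the package contains no randomness.
* Threshold and crossing searches bisect on the sucrose inflow over
  C/N ∈ [0.01, 200] (one bracket expansion ×10 before failing) to 1e-4
  relative precision.
* Residuals of fully-consumed substrates are reported as exactly 0;
  regime classification uses a 1e-9 mol m⁻³ residual tolerance. All
  tolerances live in `diazosim.constants`.
* Ties in the biomass optimum are broken toward the lower f_N2 (the cheaper
  nitrogen source).
* Degenerate inputs: zero sucrose, zero ammonium (pure diazotrophy), and
  sub-floor O₂ (washout) return explicit zero-biomass states, never NaNs;
  per-protein rates at zero biomass return an explicit undefined marker.
* The complete-drawdown closure is verified per solution: the per-cell
  fluxes it assumes are compared with the diffusive uptake ceilings at the
  inflow concentrations, and violations are attached as warnings.

## Limitations

* No Monod/transporter kinetics: residual concentrations of limiting
  substrates are idealized to ~0, so subsistence concentrations are not
  predicted.
* No maintenance energy; at a single dilution rate it is indistinguishable
  from the synthesis ATP demand.
* Steady states only; no transient chemostat dynamics, no competition
  between strains.
* One homogeneous cell type; no cell-size distribution, heterocysts or
  intracellular O₂ gradients beyond the two-compartment (medium/cytosol)
  picture.
* Per-protein absolute scales depend on the assumed cell quota and protein
  fraction; thresholds and fixation fractions do not (they are ratios of
  per-cell quantities), and no quantitative claim here rests on the
  absolute per-protein scale.
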