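# diazosim

A chemostat simulator for heterotrophic diazotrophy: an idealized
flux-balance model of an *Azotobacter vinelandii*-like bacterium growing in
continuous culture on sucrose and ammonium, fixing dinitrogen when — and only
when — the resource balance makes it pay.

Nitrogen-fixing bacteria can use both NH₄⁺ and N₂. Fixation costs extra
electrons and ATP (nitrogenase: N₂ + 8 e⁻ + 16 ATP → 2 NH₃ + H₂) and, because
nitrogenase is destroyed by oxygen, a fixing cell must respire away the
entire diffusive O₂ influx to keep its cytosol anoxic (*respiratory
protection*). `diazosim` resolves this trade-off quantitatively: it closes
mass, electron and energy balances over a coarse-grained metabolic network,
couples them to Fick-law exchange with a spherical cell, and at a fixed
dilution rate D selects the fixation fraction

    f_N2 = N from fixation / total N assimilated  ∈ [0, 1]

that maximizes the standing biomass X. The optimum is the smallest of three
quantities — the crossing of the sucrose-supported biomass
S_in/[s_g(f) + v(f)] with the ammonium-supported biomass A_in/((1−f)q), and
the oxidant cap on f — giving three regimes along the supply ratio
C/N = sucrose/ammonium (elemental C:N = 12·C/N): **A** carbon-limited growth
on ammonium, **B** ammonium-limited growth without fixation, **C** mixed
ammonium use plus fixation above an oxygen-dependent threshold C/N. The model
predicts the critical elemental ratio R_C:N for the onset of fixation to rise
from ≈ 6.7 at 1% O₂ saturation to ≈ 107 at 60% (100% = 225 µM, 30 °C).

It is intended for microbial ecophysiologists and biogeochemical modellers
who need a mechanistic, parameter-sparse rule for when diazotrophs fix
nitrogen in the presence of fixed nitrogen. See `docs/methods.md` for the
model derivation, calibration and limitations.

## Worked example

Steady state at C/N = 8 (sucrose 20 mM, ammonium 2.5 mM), 5% O₂, D = 0.15 h⁻¹:

```sh
$ diazosim solve -s 20 -a 2.5 --o2 0.05
{
 "biomass_gdw": 1896.5456441163788,
 "biomass_mol_c": 83.83189133793533,
 "f_n2": 0.8508920674399297,
 "regime": "C",
 "n_fixed": 2.13995674013806,
 "nh4_consumed": 0.375,
 "residual_nh4": 0.0,
 "sucrose_consumed": 3.0,
 "carbon_allocation": {
  "biomass_c": 1.0478986417241916,
  "synthesis_energy": 0.3234255067049974,
  "fixation_energy": 0.6186500452456737,
  "respiratory_protection": 1.0100258063251393,
  "excess_respiration": 0.0,
  "nh4_assimilation_energy": 0.0
 },
 ...
}
```

The culture is in regime C: ammonium is drawn to zero and supplies only
0.375 of the 2.515 mol N m⁻³ h⁻¹ the biomass requires, so fixation covers
f_N2 = 85% of the nitrogen demand. The carbon-allocation budget (mol sucrose
m⁻³ h⁻¹, summing to `sucrose_consumed` = 3.0) shows where the carbohydrate
goes: 35% into biomass carbon, 34% burned to scavenge oxygen (respiratory
protection), 21% powering nitrogenase, the rest powering synthesis.

The oxygen-dependent onset thresholds:

```sh
$ diazosim threshold --o2 0.01,0.05,0.6
{"thresholds": [
  {"o2_fraction": 0.01, "rc_over_n_f": 0.558, "rc_to_n_f": 6.69},
  {"o2_fraction": 0.05, "rc_over_n_f": 1.122, "rc_to_n_f": 13.46},
  {"o2_fraction": 0.60, "rc_over_n_f": 8.880, "rc_to_n_f": 106.56}]}
```

Below an elemental C:N of ≈ 6.7 fixation never pays even at 1% O₂; at 60% O₂
the substrate must be extremely nitrogen-poor (C:N ≈ 107) before fixation
starts — the extra carbon buys respiratory protection.

Other subcommands: `diazosim sweep` (grids over sucrose × ammonium × O₂, CSV
or JSON output plus regime-boundary curves), `diazosim crossing` (supply
ratio where f_N2 reaches a level), `diazosim calibrate` (refit the free
parameters; see below). `--config file.yaml` supplies any non-default
physiology or conditions; library use starts at
`diazosim.solve_steady_state`.

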