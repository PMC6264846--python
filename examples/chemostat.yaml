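# Example configuration: the reference continuous-culture setup.
# Any omitted key falls back to the shipped default (the calibrated eps_m
# among them); units are embedded in the key names.
conditions:
  dilution_rate_per_h: 0.15
  sucrose_in_mM: 20.0
  ammonium_in_mM: 2.5
  o2_fraction: 0.05        # fraction of 225 uM O2 saturation
policy: sim1               # sim2: excess respiration only while fixing
sweep:
  sucrose_in_mM: [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 37.5]
  ammonium_in_mM: [2.5]
  o2_fraction: [0.05, 0.15, 0.30, 0.60]
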