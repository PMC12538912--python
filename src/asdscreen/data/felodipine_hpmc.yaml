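# Reference drug-polymer pair: felodipine in Affinisol HPMC HME 15LV.
# All temperatures Kelvin, enthalpy J/g, densities g/cm3, molar volume
# cm3/mol, Hansen solubility parameters (J/cm3)^(1/2).
drug:
  name: felodipine
  molar_mass: 384.26
  density: 1.30
  Tm_pure: 415.25
  dH_fus_per_mass: 84.55
  Tg: 317.55
  molar_volume: 296.0
  hsp: [18.0, 11.9, 12.3]
polymer:
  name: hpmc-affinisol-15lv
  density: 1.20
  Tg: 364.67
  hsp: [22.4, 5.2, 8.4]
# Polymer-to-drug molar volume ratio of the lattice model (default; the
# polymer's own molar volume is not needed once m is fixed).
m: 100.0
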