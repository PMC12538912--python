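# asdscreen

Desk pre-screening of drug–polymer formulations for hot-melt extrusion
(HME) and FDM 3D printing of amorphous solid dispersions (ASDs).

Before committing extruder and printer time, a formulator wants two
answers: **will the drug stay amorphous in this polymer at this load and
temperature**, and **at what temperatures can the blend be extruded and
printed**? `asdscreen` answers both from bench-top inputs — DSC
melting-point-depression data, Hansen solubility parameters, and an
oscillatory rheology temperature sweep — using Flory–Huggins (F–H)
solution thermodynamics.

## The model

Mixing of a drug (volume fraction φ) with a polymer of `m`-fold molar
volume is described by the F–H free energy per lattice site

```
ΔG_mix/RT = φ ln φ + ((1−φ)/m) ln(1−φ) + χ φ(1−φ)
```

The interaction parameter χ is estimated twice:

* **near the drug's melting point** — from melting-point depression: each
  DSC endset (w, Tm_mix) maps to a point on the line
  `(1/Tm_mix − 1/Tm_pure)(ΔH_m/−R) − ln φ − (1−1/m)φ_p = χ φ_p²`,
  and the OLS slope in φ_p² is χ at Tm;
* **at ambient temperature** — from Hansen solubility parameters:
  `χ = (V₁/RT)[(δd₁−δd₂)² + 0.25(δp₁−δp₂)² + 0.25(δhb₁−δhb₂)²]`.

Fitting `χ(T) = A + B/T` through the two anchors extrapolates χ anywhere,
from which the package constructs the binary phase diagram: the
**solubility boundary** (crystalline drug in equilibrium with the melt),
the **spinodal** (`χ_s = ½(1/φ + 1/(m(1−φ)))`, inside which the amorphous
mixture demixes spontaneously), and the **Fox glass-transition curve**
(`1/Tg = X/Tg1 + (1−X)/Tg2`). Each (composition, temperature) state point
is classified stable / metastable / unstable, above or below Tg.

On the rheology side, extrusion wants the complex viscosity η* (at
0.1 rad·s⁻¹) between 1000 and 10,000 Pa·s and processing above the
G′ = G″ crossover; the package reads both off a temperature sweep.

A synthetic-data module generates all three input kinds from declared
ground truth, so the whole chain is testable as a parameter-recovery
problem without instrument data.

## Worked example

The packaged reference system is felodipine in Affinisol HPMC HME 15LV
(Tm 415.25 K, ΔH_fus 84.55 J/g, Tg 317.55/364.67 K, χ anchors 4.11 at
298 K and 0.441 at 415.25 K, m = 100):

```python
from asdscreen import (felodipine_hpmc, fit_chi_temperature_model, chi_at,
                       classify_state, solubility_boundary_at_T,
                       spinodal_composition_at_T, state_point)

mix = felodipine_hpmc()
model = fit_chi_temperature_model([(298.0, 4.11), (415.25, 0.441)])
print(model.A, model.B)
# -8.88404904051173 3872.2266140724955

T = 318.15  # stressed storage, 45 degC
print(chi_at(model, T))                           # 3.2870231395055445
print(solubility_boundary_at_T(model, mix, T))    # 0.0007902245912526204
print(spinodal_composition_at_T(model, mix.m, T)) # [0.15238679…, 0.99820539…]

for w in (0.10, 0.30):
    print(w, classify_state(state_point(mix, T, w_drug=w), model, mix))
# 0.1 ZoneLabel(stability='metastable', glass_relation='below_Tg', region_code='E')
# 0.3 ZoneLabel(stability='unstable',   glass_relation='below_Tg', region_code='H')
```

Read: at 45 °C the drug's equilibrium solubility in the polymer is tiny
(φ ≈ 8×10⁻⁴), so a 10 % w/w load (φ ≈ 0.093) is supersaturated but
outside the spinodal (lower branch φ ≈ 0.152) — metastable, protected
kinetically below the mixture Tg. A 30 % w/w load (φ ≈ 0.283) sits inside
the spinodal — unstable to demixing.

The same pipeline runs from the shell:

```sh
asdscreen simulate --out sim --seed 1          # synthetic CSV inputs
asdscreen fit-chi --depression sim/depression.csv
asdscreen rheo-window --sweep sim/sweep.csv
asdscreen report --out report --sweep sim/sweep.csv --seed 1
```

`asdscreen rheo-window` on the default synthetic sweep (built to the
reference 1:9 drug:polymer crossings) reports extrusion between 148.5 and
200.0 °C and a printing temperature of 195 °C (the 196.5 °C crossover
rounded down to the 5 °C grid), with a shear-sensitivity caveat flag —
oscillatory sweeps underestimate how processable shear-thinning cellulose
ethers are.

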