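# Methods

## Thermodynamic model

The package treats a drug–polymer blend as a binary Flory–Huggins lattice
solution. With φ the drug volume fraction and `m` the polymer-to-drug
molar-volume ratio,

    ΔG_mix/RT = φ ln φ + ((1−φ)/m) ln(1−φ) + χ φ(1−φ).

The entropic terms are continuously extended to 0 at φ ∈ {0, 1}. The
model assumes a composition-independent χ, incompressibility, and a
single amorphous phase; ternary additives, plasticizers and
composition-dependent χ(φ) are out of scope.

### χ from melting-point depression

A crystalline drug dissolving into a polymer melts lower. Equating the
chemical potential of crystalline drug with that of drug in solution and
rearranging gives a line through the origin,

    y ≡ (1/Tm_mix − 1/Tm_pure)(ΔH_m/−R) − ln φ − (1 − 1/m) φ_p = χ φ_p²,

so χ at the drug's melting point is the slope of y against φ_p². The
regression keeps a **free intercept** as a diagnostic: the model predicts
zero, and |intercept| > 0.1 triggers a misfit warning. ΔH_m is the molar
fusion enthalpy; DSC reports J·g⁻¹, so the per-mass value is multiplied
by the molar mass (felodipine: 84.55 J/g × 384.26 g/mol ≈ 32,489 J/mol).
Points with zero drug content (ln φ undefined) or apparent melting
*elevation* (Tm_mix > Tm_pure) are dropped with a warning. Note that for
sufficiently positive χ the relation itself predicts elevation at
drug-rich compositions (the bracket changes sign near φ → 1); the
generator will happily produce such data, and the transform's rejection
rule then prunes them — parameter-recovery checks therefore use χ values
for which the whole composition grid shows depression.

### χ from Hansen solubility parameters

At ambient temperature, where no melting event exists,

    χ = (V₁/RT)[(δd₁−δd₂)² + 0.25(δp₁−δp₂)² + 0.25(δhb₁−δhb₂)²],

with V₁ the drug molar volume (cm³·mol⁻¹) and δ in (J·cm⁻³)^½, making
V₁δ² J·mol⁻¹. Non-negative by construction, zero only for identical
triples.

### Temperature extrapolation

χ(T) = A + B/T is fitted by least squares of χ against 1/T; with exactly
two anchors this is the exact 2×2 solve. The canonical felodipine–HPMC
anchors are (298 K, 4.11) and (415.25 K, 0.441) — 298 K (not 298.15) is
kept deliberately because the reference coefficients are only reproduced
with those exact values; the general API converts °C with +273.15. The
solve gives A = −8.884, B = +3872.23 K. A is stored **signed**: the
published magnitude 8.88 is only consistent with the two anchors if A is
negative, so comparison output reports |A|.

## Phase-diagram construction

* **Spinodal**: ∂²(ΔG_mix/RT)/∂φ² = 0 gives χ_s(φ) = ½(1/φ + 1/(m(1−φ)))
  in closed form; at temperature T the boundary compositions solve
  χ_s(φ) = χ(T), bracketed on either side of the critical composition
  φ_c = √m/(1+√m) (χ_c = (1+√m)²/2m → ½ for long chains). No solution
  when χ(T) < χ_c — the pair is miscible at every composition.
* **Solubility boundary**: the depression relation read at temperature T
  and solved for φ by bracketed root-finding (Brent, bracket
  (10⁻⁸, 1−10⁻⁸), xtol 10⁻¹⁰ in φ); exactly 1 at T = Tm_pure. Absence of
  a sign change is reported as "no solubility limit", not an error.
* **Tg curve**: Fox form 1/Tg = X/Tg1 + (1−X)/Tg2 in weight fraction.
  The Gordon–Taylor variant with a fitted K is deliberately not offered.

Grid-point solver failures during diagram sampling are recorded as gaps
and never abort the diagram.

### Zone classification

Contractual outputs per state point: `stability` (stable at or below the
solubility boundary; unstable when χ(T) exceeds χ_s at that composition;
metastable between) and `glass_relation` (T vs the Fox Tg of that
composition). A cosmetic nine-letter `region_code` mirrors the
conventional sketch: stable A/B (above/below Tg), metastable C/D (above
Tg, split at the upper temperature third) and E (below Tg), unstable G
(above Tg) and H/I (below Tg, I reserved for the coldest 10 % of the
diagram's temperature span). Only the letters are conventional; the
stability and glass relation carry the science.

## Rheology windows

Extrudability band: η* within 1000–10,000 Pa·s at 0.1 rad·s⁻¹;
processability above the G′ = G″ crossover (tan δ = 1). Crossings are
interpolated linearly in (T, log modulus) because the quantities span
decades. The printing temperature rule is "crossover rounded down to the
nearest 5 °C", codified from the reference system's worked choice
(196.5 → 195 °C) and exposed as a strategy option (`"crossover"` returns
the crossover itself). Every window carries a shear-sensitivity caveat
flag: oscillatory data sample low shear rates, and shear-thinning
cellulose ethers are routinely processed below the oscillatory window; no
shear-rate superposition is attempted.

## DSC endset detection

The depressed melting point is the endset — where the endothermic trace
rejoins the baseline after melting. Procedure: (1) locate the endotherm
on a whole-trace linear detrend (insensitive to any affine baseline and
to a misplaced window) and require its height to exceed 6× a
point-to-point noise floor (1.4826·MAD of successive differences /√2),
else "no melting event"; (2) fit the instrument baseline by OLS over a
user-supplied post-melting window (error if the peak lies inside it);
(3) walk the trailing edge from the peak to the first sample within 3×
the baseline-residual RMS of the baseline and interpolate linearly to the
exact band crossing. In the noise-free limit the band collapses and the
rule reduces to the geometric trace/baseline intersection. Exo-up traces
are sign-normalised on input; only second-heating-cycle traces are
modelled. Endsets above the pure drug's Tm are excluded at assembly time
with a provenance record.

## Synthetic data

The generators emulate the three instrument inputs with fully declared
ground truth; all randomness flows from one integer seed (an identical
spec reproduces identical bytes), with independent substreams per
product.

* **Depression tables**: the depression relation inverted for Tm_mix
  under a true χ, plus additive Gaussian noise on each melting point
  (default σ = 0.3 K, a realistic endset repeatability). Default
  composition grid w ∈ {0.5,…,1.0}: depression fits need drug-rich
  mixtures where a melting event exists. Defaults describe the reference
  system: χ_true = 0.441, m = 100, Tm 415.25 K, ΔH_m 32,489 J/mol.
* **Thermograms**: linear baseline + endotherm rising as a half-Gaussian
  and falling along a concave quadratic that meets the baseline *exactly*
  at the prescribed endset, so ground truth is the geometric
  intersection the detector targets; additive Gaussian noise (default
  0.05 signal units, 0.5 % of the 10-unit peak).
* **Sweeps**: log₁₀ G′, G″, η* linear in temperature, constructed through
  prescribed crossover and viscosity-threshold temperatures (defaults:
  the reference 1:9 blend — 10⁴ Pa·s at 148.5 °C, 10³ Pa·s at 200.0 °C,
  crossover 196.5 °C at 10⁴ Pa); multiplicative log-normal noise
  (default 1 %).

What the generators do **not** emulate: peak shape families beyond the
single asymmetric endotherm (no shoulders, no polymorph doublets, no
first-cycle moisture endotherms), baseline curvature, instrument lag at
different scan rates, frequency dependence of moduli, and any
composition–viscosity coupling. Passing recovery tests therefore shows
the analysis chain is correct and noise-robust at realistic noise levels,
not that it is robust to every pathology of real traces.

## Numerical choices and problem sizes

* Root-finding: Brent bisection everywhere, bracket (10⁻⁸, 1−10⁻⁸) in φ,
  xtol 10⁻¹⁰; spinodal roots searched on each side of φ_c.
* φ ln φ at 0 defined as 0; all internal temperatures Kelvin; CSV/CLI
  accept °C via an explicit unit column/flag.
* Test oracles: the spinodal closed form is cross-checked against the
  root (in χ) of a five-point finite-difference second derivative of
  ΔG_mix (h = 10⁻⁴); boundary solvers against dense-grid sign-change
  scans (2×10⁵–4×10⁵ points).
* Parameter-recovery spread: a 200-seed Monte-Carlo at σ = 0.3 K over six
  compositions gives a χ-slope sampling sd of ≈7 % with a small positive
  bias (≈2 %), driven mostly by noise on the drug-rich anchor points and
  occasional rejection of the noised pure-drug point; recovery assertions
  are therefore made on the Monte-Carlo aggregate (median error, mean
  estimate), with the noise-free chain exact to 10⁻⁶.
* Phase diagrams default to an 80-point temperature grid from 298.15 K to
  the drug's melting point — converged well past the reported precision
  while keeping diagram construction interactive.

## Known limitations

* The two-anchor χ(T) model inherits the full uncertainty of both
  anchors; B shifts by ≈1000 K per unit error in either χ.
* The published weight-fraction stability boundary of 0.29 for the
  reference system is not recoverable from the printed constants under
  any single m and is not used as a check; classification checks use the
  spinodal and solubility boundaries directly (robust for m ≥ 20).
* The published depression-plot slope (−0.0104) is mutually inconsistent
  with the published χ = 0.441 under the transform as written; this
  package always reports the OLS slope as χ and takes 0.441 only as the
  χ(T) anchor value for the reference system.
* Oscillatory windows are starting points, not guarantees: shear-rate
  effects in the extruder and printer nozzle can widen or shift them.
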