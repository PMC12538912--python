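"""Flory-Huggins thermodynamics for binary drug-polymer dispersions.

The lattice model describes mixing of a small-molecule drug (volume
fraction φ) with a polymer whose molar volume is ``m`` times larger:

    ΔG_mix / RT = φ ln φ + ((1 − φ)/m) ln(1 − φ) + χ φ (1 − φ)

Everything in this module derives from that expression and from two routes
to the interaction parameter χ:

* **melting-point depression** — the drug's depressed melting point in
  drug-rich mixtures, rearranged so that χ is the slope of a straight line
  in φ_polymer², gives χ near the drug's melting point;
* **Hansen solubility parameters** — the cohesive-energy-density mismatch
  gives χ at ambient temperature.

Fitting χ = A + B/T through those two anchors extrapolates χ to any
temperature, from which the spinodal (miscibility) boundary, the crystalline
solubility boundary, the Fox glass-transition curve, and a zone-labelled
phase diagram follow.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .components import BinaryMixture, Component, StatePoint, state_point
from .constants import R

__all__ = [
    "delta_g_mix", "spinodal_chi", "critical_point",
    "MeltingDepressionDataset", "depression_transform", "fit_chi_at_tm",
    "ChiFitResult", "chi_from_hsp", "ChiTemperatureModel",
    "fit_chi_temperature_model", "chi_at", "spinodal_composition_at_T",
    "solubility_boundary_at_T", "tg_mixture", "ZoneLabel", "classify_state",
    "PhaseDiagram", "build_phase_diagram",
]

# Bracket used by every bisection on a volume fraction; the free energy and
# spinodal expressions diverge logarithmically at the pure endpoints.
_PHI_EPS = 1e-8
_PHI_XTOL = 1e-10


def _xlogx(x: np.ndarray | float):
    """x·ln(x) with the continuous extension 0 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    positive = x > 0
    out[positive] = x[positive] * np.log(x[positive])
    return out


def delta_g_mix(phi_drug, m: float, chi: float):
    """Dimensionless free energy of mixing ΔG_mix/RT.

    Parameters
    ----------
    phi_drug:
        Drug volume fraction in [0, 1]; scalar or array.
    m:
        Polymer-to-drug molar volume ratio, ≥ 1.
    chi:
        Flory-Huggins interaction parameter (dimensionless).

    Returns
    -------
    φ ln φ + ((1−φ)/m) ln(1−φ) + χ φ (1−φ), with the entropy terms
    continuously extended to 0 at the pure-component endpoints.
    """
    phi = np.asarray(phi_drug, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi_drug must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    g = _xlogx(phi) + _xlogx(1.0 - phi) / m + chi * phi * (1.0 - phi)
    if np.isscalar(phi_drug):
        return float(g)
    return g


def spinodal_chi(phi_drug: float, m: float) -> float:
    """Interaction parameter on the spinodal at composition φ.

    Setting the second composition derivative of ΔG_mix/RT to zero gives
    the closed form χ_s(φ) = ½ (1/φ + 1/(m(1−φ))).  For χ above this value
    the homogeneous mixture at φ is unstable to spontaneous demixing.
    """
    if not 0.0 < phi_drug < 1.0:
        raise ValueError(
            f"spinodal diverges at the pure endpoints; got phi={phi_drug}")
    return 0.5 * (1.0 / phi_drug + 1.0 / (m * (1.0 - phi_drug)))


def critical_point(m: float) -> Tuple[float, float]:
    """Critical composition and interaction parameter, (φ_c, χ_c).

    The minimum of the spinodal: φ_c = √m/(1+√m), χ_c = (1+√m)²/(2m).
    χ_c → ½ in the long-chain limit, the classic criterion that χ below
    one half implies miscibility at every composition.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    sqrt_m = math.sqrt(m)
    phi_c = sqrt_m / (1.0 + sqrt_m)
    chi_c = (1.0 + sqrt_m) ** 2 / (2.0 * m)
    return phi_c, chi_c


# --- melting-point depression ------------------------------------------------

@dataclass
class MeltingDepressionDataset:
    """Depressed melting points of drug-rich mixtures.

    ``points`` holds (drug weight fraction, mixture melting point in K)
    pairs; melting points must not exceed the pure drug's, and at least
    three distinct compositions are needed for a regression.
    """

    points: List[Tuple[float, float]]
    provenance: str = ""

    def validate(self, Tm_pure: Optional[float] = None) -> None:
        if len(self.points) < 3:
            raise ValueError(
                f"need at least 3 depression points, got {len(self.points)}")
        ws = [w for w, _ in self.points]
        if len(set(ws)) != len(ws):
            raise ValueError("depression compositions must be distinct")
        if Tm_pure is not None:
            bad = [(w, t) for w, t in self.points if t > Tm_pure]
            if bad:
                raise ValueError(
                    f"melting elevation is unphysical here: {bad} exceed "
                    f"Tm_pure={Tm_pure} K")


def depression_transform(
    dataset: MeltingDepressionDataset, mixture: BinaryMixture,
) -> List[Tuple[float, float]]:
    """Linearise melting-point-depression data for the χ regression.

    Each (w, Tm_mix) point maps to (x, y) with

        y = (1/Tm_mix − 1/Tm_pure)(ΔH_m/−R) − ln φ_drug − (1 − 1/m) φ_polymer
        x = φ_polymer²

    so that y = χ·x when the lattice model holds with a composition-
    independent χ; the regression slope of y on x is χ at the drug's
    melting point.  Points with zero drug content (ln φ undefined) or with
    melting elevation are dropped with a warning rather than poisoning the
    fit.
    """
    drug = mixture.drug
    drug.require("Tm_pure", "dH_fus_per_mass", "molar_mass")
    dH = drug.dH_fus_molar
    out: List[Tuple[float, float]] = []
    for w, tm_mix in dataset.points:
        if w <= 0.0:
            warnings.warn(f"dropping point w_drug={w}: ln(phi) undefined")
            continue
        if tm_mix > drug.Tm_pure:
            warnings.warn(
                f"dropping point w_drug={w}: Tm_mix={tm_mix} K exceeds "
                f"Tm_pure={drug.Tm_pure} K (elevation, not depression)")
            continue
        phi = mixture.volume_fraction_from_weight(w)
        phi_p = 1.0 - phi
        y = ((1.0 / tm_mix - 1.0 / drug.Tm_pure) * (dH / -R)
             - math.log(phi) - (1.0 - 1.0 / mixture.m) * phi_p)
        out.append((phi_p ** 2, y))
    return out


@dataclass(frozen=True)
class ChiFitResult:
    """Result of the depression regression: slope is χ at the drug's Tm."""

    chi_at_tm: float
    intercept: float
    r_squared: float
    n_points: int

    #: an intercept this far from zero flags lattice-model misfit
    INTERCEPT_WARN: ClassVar[float] = 0.1


def fit_chi_at_tm(transformed: Sequence[Tuple[float, float]]) -> ChiFitResult:
    """Ordinary least squares of the linearised depression data.

    The slope is reported as χ at the melting point of the pure drug.  The
    intercept is left free and reported as a diagnostic: the model predicts
    it to be zero, so a large magnitude signals that the data do not follow
    the lattice form.
    """
    if len(transformed) < 3:
        raise ValueError(
            f"need at least 3 transformed points, got {len(transformed)}")
    x = np.array([p[0] for p in transformed])
    y = np.array([p[1] for p in transformed])
    if np.ptp(x) == 0:
        raise ValueError("all x values equal; slope is undefined")
    fit = linregress(x, y)
    if abs(fit.intercept) > ChiFitResult.INTERCEPT_WARN:
        warnings.warn(
            f"depression-fit intercept {fit.intercept:.3g} exceeds "
            f"{ChiFitResult.INTERCEPT_WARN}; lattice model may not describe "
            f"these data")
    return ChiFitResult(chi_at_tm=float(fit.slope),
                        intercept=float(fit.intercept),
                        r_squared=float(fit.rvalue ** 2),
                        n_points=len(transformed))


# --- Hansen-parameter route --------------------------------------------------

def chi_from_hsp(drug: Component, polymer: Component, T: float) -> float:
    """Interaction parameter from Hansen solubility parameters.

    χ = (V1/RT) [(δ_d1 − δ_d2)² + 0.25 (δ_p1 − δ_p2)² + 0.25 (δ_h1 − δ_h2)²]

    with V1 the drug molar volume in cm³·mol⁻¹ and δ in (J·cm⁻³)^½ so the
    product V1·δ² is J·mol⁻¹.  Non-negative by construction; zero only when
    the two triples coincide.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    drug.require("hsp", "molar_volume")
    polymer.require("hsp")
    d1, p1, h1 = drug.hsp
    d2, p2, h2 = polymer.hsp
    mismatch = (d1 - d2) ** 2 + 0.25 * (p1 - p2) ** 2 + 0.25 * (h1 - h2) ** 2
    return drug.molar_volume / (R * T) * mismatch


# --- temperature extrapolation ----------------------------------------------

@dataclass(frozen=True)
class ChiTemperatureModel:
    """The two-parameter temperature model χ(T) = A + B/T.

    ``A`` is the temperature-independent (entropic) term and is stored
    *signed*; ``B`` (in K) carries the enthalpic temperature dependence.
    ``anchors`` records the (T, χ) pairs the model was fitted through.
    """

    A: float
    B: float
    anchors: Tuple[Tuple[float, float], ...] = ()

    def __call__(self, T: float) -> float:
        return chi_at(self, T)


def fit_chi_temperature_model(
    anchors: Sequence[Tuple[float, float]],
) -> ChiTemperatureModel:
    """Fit χ = A + B/T by least squares of χ against 1/T.

    With exactly two anchors this reduces to the exact linear solve through
    both points; with more it is the OLS fit.  At least two distinct
    temperatures are required.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 (T, chi) anchors")
    T = np.array([a[0] for a in anchors], dtype=float)
    chi = np.array([a[1] for a in anchors], dtype=float)
    if np.any(T <= 0):
        raise ValueError("anchor temperatures must be positive (K)")
    if len(np.unique(T)) < 2:
        raise ValueError("anchors must span at least 2 distinct temperatures")
    inv_T = 1.0 / T
    if len(anchors) == 2:
        b = (chi[0] - chi[1]) / (inv_T[0] - inv_T[1])
        a = chi[0] - b * inv_T[0]
    else:
        coeffs = np.polyfit(inv_T, chi, 1)
        b, a = float(coeffs[0]), float(coeffs[1])
    return ChiTemperatureModel(A=float(a), B=float(b),
                               anchors=tuple((float(t), float(c))
                                             for t, c in anchors))


def chi_at(model: ChiTemperatureModel, T: float) -> float:
    """Evaluate χ(T) = A + B/T."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return model.A + model.B / T


# --- boundary solvers --------------------------------------------------------

def spinodal_composition_at_T(
    model: ChiTemperatureModel, m: float, T: float,
) -> List[float]:
    """Volume fractions on the spinodal at temperature T.

    Solves χ_s(φ, m) = χ(T) on each side of the critical composition.
    Returns an empty list when χ(T) is below the critical value (the pair
    is miscible at every composition at that temperature), one root at
    tangency, otherwise the two spinodal branches in increasing order.
    """
    chi_T = chi_at(model, T)
    phi_c, chi_c = critical_point(m)
    if chi_T < chi_c:
        return []
    if math.isclose(chi_T, chi_c, rel_tol=0.0, abs_tol=1e-12):
        return [phi_c]

    def f(phi: float) -> float:
        return spinodal_chi(phi, m) - chi_T

    roots: List[float] = []
    for lo, hi in ((_PHI_EPS, phi_c), (phi_c, 1.0 - _PHI_EPS)):
        if f(lo) * f(hi) < 0:
            roots.append(float(brentq(f, lo, hi, xtol=_PHI_XTOL)))
    return sorted(roots)


def solubility_boundary_at_T(
    model: ChiTemperatureModel, mixture: BinaryMixture, T: float,
) -> Optional[float]:
    """Crystalline-drug solubility (volume fraction) in the polymer at T.

    The melting-point-depression relation read at temperature T and solved
    for composition: the φ_drug in (0, 1] satisfying

        (1/T − 1/Tm_pure)(ΔH_m/−R) = ln φ + (1 − 1/m)(1 − φ) + χ(T)(1 − φ)²

    Returns 1.0 exactly at T = Tm_pure (the pure drug melts at its own
    melting point) and ``None`` when no sign change exists in (0, 1) —
    a valid "no solubility limit" outcome, not an error.
    """
    drug = mixture.drug
    drug.require("Tm_pure", "dH_fus_per_mass", "molar_mass")
    if not 0.0 < T <= drug.Tm_pure:
        raise ValueError(
            f"T must lie in (0, Tm_pure={drug.Tm_pure}]; got {T}")
    if math.isclose(T, drug.Tm_pure):
        return 1.0
    lhs = (1.0 / T - 1.0 / drug.Tm_pure) * (drug.dH_fus_molar / -R)
    chi_T = chi_at(model, T)
    m = mixture.m

    def f(phi: float) -> float:
        return (math.log(phi) + (1.0 - 1.0 / m) * (1.0 - phi)
                + chi_T * (1.0 - phi) ** 2 - lhs)

    lo, hi = _PHI_EPS, 1.0 - _PHI_EPS
    if f(lo) * f(hi) > 0:
        return None
    return float(brentq(f, lo, hi, xtol=_PHI_XTOL))


def tg_mixture(X: float, Tg1: float, Tg2: float) -> float:
    """Fox-equation glass-transition temperature of the mixture.

    1/Tg = X/Tg1 + (1 − X)/Tg2, with X the drug weight fraction.  The
    result is the weight-harmonic mean of the two pure-component Tg values
    and is monotone in X.
    """
    if not 0.0 <= X <= 1.0:
        raise ValueError(f"weight fraction must lie in [0, 1], got {X}")
    if Tg1 <= 0 or Tg2 <= 0:
        raise ValueError("glass-transition temperatures must be positive (K)")
    return 1.0 / (X / Tg1 + (1.0 - X) / Tg2)


# --- zone classification -----------------------------------------------------

@dataclass(frozen=True)
class ZoneLabel:
    """Stability classification of one state point.

    ``stability`` and ``glass_relation`` are the contractual outputs:
    *stable* below the crystalline solubility limit, *unstable* inside the
    spinodal, *metastable* in between, and above/below the Fox Tg curve.
    ``region_code`` is a best-effort letter A-I locating the point on the
    conventional nine-region phase-diagram sketch.
    """

    stability: str
    glass_relation: str
    region_code: str


# Letter grid: stable rows A (above Tg) / B (below); metastable C/D above
# Tg split at the upper temperature third, E below Tg; unstable G above Tg,
# H/I below Tg with I reserved for the coldest band.  Only the letters are
# conventional; stability and glass relation carry the meaning.
def _region_code(stability: str, above_tg: bool, T: float,
                 t_range: Tuple[float, float]) -> str:
    t_lo, t_hi = t_range
    span = max(t_hi - t_lo, 1e-9)
    if stability == "stable":
        return "A" if above_tg else "B"
    if stability == "metastable":
        if not above_tg:
            return "E"
        return "C" if T >= t_hi - span / 3.0 else "D"
    if above_tg:
        return "G"
    return "I" if T <= t_lo + 0.1 * span else "H"


def classify_state(
    point: StatePoint,
    model: ChiTemperatureModel,
    mixture: BinaryMixture,
    t_range: Optional[Tuple[float, float]] = None,
) -> ZoneLabel:
    """Classify a state point as stable, metastable, or unstable.

    * **stable** — drug volume fraction at or below the crystalline
      solubility boundary at that temperature;
    * **unstable** — χ(T) above the spinodal value at that composition
      (spontaneous amorphous-amorphous demixing);
    * **metastable** — between the two boundaries: demixing requires
      nucleation.

    ``glass_relation`` compares T with the Fox Tg of the mixture;
    ``t_range`` (default 298.15 K to the drug's melting point) only
    influences the cosmetic region letter.
    """
    drug, polymer = mixture.drug, mixture.polymer
    if t_range is None:
        t_range = (298.15, drug.Tm_pure if drug.Tm_pure else point.T)
    try:
        phi_sol = solubility_boundary_at_T(model, mixture, point.T)
    except ValueError as exc:
        raise RuntimeError(
            f"solubility solve failed at state point {point}") from exc

    if phi_sol is not None and point.phi_drug <= phi_sol:
        stability = "stable"
    elif (0.0 < point.phi_drug < 1.0
          and chi_at(model, point.T) > spinodal_chi(point.phi_drug, mixture.m)):
        stability = "unstable"
    else:
        stability = "metastable"

    drug.require("Tg")
    polymer.require("Tg")
    tg = tg_mixture(point.w_drug, drug.Tg, polymer.Tg)
    above_tg = point.T >= tg
    return ZoneLabel(
        stability=stability,
        glass_relation="above_Tg" if above_tg else "below_Tg",
        region_code=_region_code(stability, above_tg, point.T, t_range),
    )


# --- phase-diagram construction ---------------------------------------------

@dataclass
class PhaseDiagram:
    """Sampled solubility, spinodal, and Tg curves with a zone classifier.

    ``solubility_curve`` and ``spinodal_curve`` are (φ, T) sample lists,
    ``tg_curve`` is (w, T); ``gaps`` records grid temperatures where a
    boundary solve failed or returned nothing.  ``classify`` labels an
    arbitrary state point with the same model and mixture the curves were
    built from.
    """

    T_grid: np.ndarray
    solubility_curve: List[Tuple[float, float]]
    spinodal_curve: List[Tuple[float, float]]
    tg_curve: List[Tuple[float, float]]
    model: ChiTemperatureModel
    mixture: BinaryMixture
    gaps: List[Tuple[str, float]] = field(default_factory=list)

    def classify(self, point: StatePoint) -> ZoneLabel:
        t_range = (float(self.T_grid[0]), float(self.T_grid[-1]))
        return classify_state(point, self.model, self.mixture, t_range)

    def to_dict(self) -> dict:
        return {
            "model": {"A": self.model.A, "B": self.model.B},
            "curves": {
                "solubility": [[p, t] for p, t in self.solubility_curve],
                "spinodal": [[p, t] for p, t in self.spinodal_curve],
                "tg": [[w, t] for w, t in self.tg_curve],
            },
            "grid": {
                "T_min": float(self.T_grid[0]),
                "T_max": float(self.T_grid[-1]),
                "n_T": int(len(self.T_grid)),
            },
            "gaps": [[kind, t] for kind, t in self.gaps],
            "provenance": {
                "drug": self.mixture.drug.name,
                "polymer": self.mixture.polymer.name,
                "m": self.mixture.m,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def build_phase_diagram(
    model: ChiTemperatureModel,
    mixture: BinaryMixture,
    t_range: Optional[Tuple[float, float]] = None,
    n_T: int = 80,
    n_w: int = 51,
) -> PhaseDiagram:
    """Sample the three phase-diagram curves over a temperature grid.

    Individual grid-point solver failures are recorded in ``gaps`` and do
    not abort the construction; an empty spinodal curve (every temperature
    miscible) still yields a valid diagram.
    """
    drug = mixture.drug
    drug.require("Tm_pure")
    if t_range is None:
        t_range = (298.15, drug.Tm_pure)
    t_lo, t_hi = t_range
    if not 0.0 < t_lo < t_hi <= drug.Tm_pure:
        raise ValueError(
            f"t_range must satisfy 0 < T_min < T_max <= Tm_pure; got {t_range}")
    T_grid = np.linspace(t_lo, t_hi, n_T)

    solubility: List[Tuple[float, float]] = []
    spinodal: List[Tuple[float, float]] = []
    gaps: List[Tuple[str, float]] = []
    for T in T_grid:
        try:
            phi_sol = solubility_boundary_at_T(model, mixture, float(T))
        except (ValueError, RuntimeError):
            phi_sol = None
        if phi_sol is None:
            gaps.append(("solubility", float(T)))
        else:
            solubility.append((phi_sol, float(T)))
        try:
            roots = spinodal_composition_at_T(model, mixture.m, float(T))
        except (ValueError, RuntimeError):
            roots = []
            gaps.append(("spinodal", float(T)))
        for phi in roots:
            spinodal.append((phi, float(T)))

    tg_curve: List[Tuple[float, float]] = []
    if drug.Tg is not None and mixture.polymer.Tg is not None:
        for w in np.linspace(0.0, 1.0, n_w):
            tg_curve.append((float(w),
                             tg_mixture(float(w), drug.Tg, mixture.polymer.Tg)))

    return PhaseDiagram(T_grid=T_grid, solubility_curve=solubility,
                        spinodal_curve=spinodal, tg_curve=tg_curve,
                        model=model, mixture=mixture, gaps=gaps)
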