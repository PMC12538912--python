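"""Synthetic instrument data with known ground truth.

No raw instrument data ships with this package; instead every input the
pipeline consumes can be generated from a declared ground truth so each
analysis stage is testable as a parameter-recovery problem:

* **melting-point depression tables** — the depression relation inverted
  under a chosen true χ, plus additive Gaussian temperature noise;
* **DSC thermograms** — a linear instrument baseline plus an asymmetric
  melting endotherm whose trailing edge returns to baseline at a
  prescribed endset;
* **oscillatory sweeps** — log-linear-in-temperature moduli and complex
  viscosity constructed to pass through prescribed crossover and
  viscosity-threshold temperatures.

All randomness flows from the single ``seed`` field: an identical spec
yields byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .components import BinaryMixture
from .constants import R, celsius_to_kelvin
from .dsc import Thermogram
from .rheology import OscillatorySweep
from .thermo import MeltingDepressionDataset


class GenerationError(ValueError):
    """The requested parameter combination yields unphysical data."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise levels for all three generators.

    Defaults describe a felodipine-like crystalline drug (Tm 415.25 K,
    molar fusion enthalpy 32,489 J/mol) dispersed in a long-chain polymer
    (m = 100) with a weakly positive interaction (χ = 0.441 at the drug's
    melting point), probed on a drug-rich composition grid where a melting
    event exists, with 0.3 K of temperature noise on each depressed
    melting point.
    """

    # melting-point depression
    chi_true: float = 0.441
    m: float = 100.0
    Tm_pure: float = 415.25
    dH_molar: float = 84.55 * 384.26  # J/mol
    compositions: Tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    noise_sd_T: float = 0.3  # K, additive on Tm_mix

    # thermogram shape
    scan_range: Tuple[float, float] = (350.0, 430.0)  # K
    scan_step: float = 0.1          # K between samples
    baseline_slope: float = 0.002   # signal units per K
    baseline_intercept: float = 0.5
    peak_amplitude: float = 10.0    # signal units above baseline
    peak_width: float = 4.0         # K, trailing-edge length (peak to endset)
    thermogram_noise_sd: float = 0.05  # signal units, additive

    # oscillatory sweep construction (°C where noted)
    sweep_range_C: Tuple[float, float] = (130.0, 230.0)
    sweep_step_C: float = 0.5
    t_eta_upper_C: float = 148.5    # T where eta* = 10^4 Pa.s
    t_eta_lower_C: float = 200.0    # T where eta* = 10^3 Pa.s
    crossover_C: float = 196.5      # T where G' = G''
    g_crossover: float = 1.0e4      # Pa, common modulus at the crossover
    logG_storage_slope: float = -0.040  # log10 Pa per °C
    logG_loss_slope: float = -0.020     # log10 Pa per °C
    sweep_noise_rel: float = 0.01   # lognormal sigma, multiplicative

    seed: int = 0


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # distinct stream per generator so adding one product never perturbs
    # another product drawn from the same spec
    return np.random.default_rng([spec.seed, stream])


def invert_depression(phi_drug: float, spec: SyntheticSpec) -> float:
    """Noise-free depressed melting point at drug volume fraction φ.

    Solves the depression relation for Tm_mix:
    1/Tm_mix = 1/Tm_pure + (−R/ΔH_m)[ln φ + (1 − 1/m)(1 − φ) + χ(1 − φ)²].
    """
    if not 0.0 < phi_drug <= 1.0:
        raise GenerationError(f"phi_drug must lie in (0, 1], got {phi_drug}")
    if phi_drug == 1.0:
        return spec.Tm_pure
    bracket = (math.log(phi_drug)
               + (1.0 - 1.0 / spec.m) * (1.0 - phi_drug)
               + spec.chi_true * (1.0 - phi_drug) ** 2)
    inv_tm = 1.0 / spec.Tm_pure + (-R / spec.dH_molar) * bracket
    if inv_tm <= 0:
        raise GenerationError(
            f"parameters yield non-positive melting point at phi={phi_drug}")
    return 1.0 / inv_tm


def simulate_melting_depression(
    spec: SyntheticSpec, mixture: BinaryMixture,
) -> MeltingDepressionDataset:
    """Generate a depression table under the spec's true χ.

    Compositions are weight fractions, converted to volume fractions with
    the mixture's densities; Gaussian noise of sd ``noise_sd_T`` (K) is
    added to every melting point, including the pure-drug anchor — the
    downstream transform is expected to reject apparent elevation.
    """
    rng = _rng(spec, stream=1)
    points: List[Tuple[float, float]] = []
    for w in spec.compositions:
        if not 0.0 < w <= 1.0:
            raise GenerationError(f"composition must lie in (0, 1], got {w}")
        phi = mixture.volume_fraction_from_weight(w)
        tm = invert_depression(phi, spec)
        if spec.noise_sd_T > 0:
            tm += rng.normal(0.0, spec.noise_sd_T)
        if tm <= 0:
            raise GenerationError(f"noise drove Tm_mix non-positive at w={w}")
        points.append((float(w), float(tm)))
    return MeltingDepressionDataset(
        points=points,
        provenance=(f"synthetic depression: chi_true={spec.chi_true}, "
                    f"m={spec.m}, noise_sd_T={spec.noise_sd_T} K, "
                    f"seed={spec.seed}"),
    )


def simulate_thermogram(spec: SyntheticSpec, target_endset: float) -> Thermogram:
    """Generate a heating trace whose melting endset is ``target_endset``.

    The endotherm rises as a half-Gaussian to its peak at
    ``target_endset − peak_width`` and falls along a concave quadratic that
    meets the baseline *exactly* at ``target_endset`` — so the prescribed
    endset is the geometric trace/baseline intersection, the ground truth
    the detector is meant to recover.  Additive Gaussian noise of sd
    ``thermogram_noise_sd`` is applied to the whole trace.
    """
    lo, hi = spec.scan_range
    if not lo < target_endset < hi:
        raise GenerationError(
            f"target endset {target_endset} K outside scan range {spec.scan_range}")
    peak_T = target_endset - spec.peak_width
    if peak_T - 3.0 * spec.peak_width <= lo or target_endset >= hi - 2.0:
        raise GenerationError(
            f"peak of width {spec.peak_width} K does not fit inside "
            f"scan range {spec.scan_range}")
    T = np.arange(lo, hi + 0.5 * spec.scan_step, spec.scan_step)
    baseline = spec.baseline_intercept + spec.baseline_slope * T

    signal = np.zeros_like(T)
    rising = T <= peak_T
    sigma = spec.peak_width  # rising-edge width; melting onset is gradual
    signal[rising] = np.exp(-0.5 * ((T[rising] - peak_T) / sigma) ** 2)
    falling = (T > peak_T) & (T < target_endset)
    u = (T[falling] - peak_T) / spec.peak_width
    signal[falling] = 1.0 - u ** 2
    signal *= spec.peak_amplitude

    heat_flow = baseline + signal
    if spec.thermogram_noise_sd > 0:
        rng = _rng(spec, stream=2)
        heat_flow = heat_flow + rng.normal(0.0, spec.thermogram_noise_sd,
                                           size=heat_flow.shape)
    return Thermogram(T=T, heat_flow=heat_flow, scan_rate=10.0, exo_up=False)


def simulate_depression_thermograms(
    spec: SyntheticSpec, mixture: BinaryMixture,
) -> List[Tuple[float, Thermogram]]:
    """Thermograms across the composition grid, endsets on the true
    depression curve.

    The end-to-end fixture: each composition's thermogram has its melting
    endset at the noise-free depressed melting point, so running endset
    detection and the χ regression over the set should recover
    ``chi_true`` to within the detector tolerance.
    """
    out: List[Tuple[float, Thermogram]] = []
    for i, w in enumerate(spec.compositions):
        phi = mixture.volume_fraction_from_weight(w)
        tm = invert_depression(phi, spec)
        sub = replace(spec, seed=spec.seed + i)  # independent noise per trace
        out.append((float(w), simulate_thermogram(sub, target_endset=tm)))
    return out


def simulate_sweep(spec: SyntheticSpec) -> OscillatorySweep:
    """Generate an oscillatory temperature sweep with prescribed crossings.

    log₁₀ η* falls linearly in temperature through
    (``t_eta_upper_C``, 10⁴ Pa·s) and (``t_eta_lower_C``, 10³ Pa·s);
    log₁₀ G′ and log₁₀ G″ fall linearly with the configured slopes and
    intersect at (``crossover_C``, ``g_crossover``).  Multiplicative
    log-normal noise of relative sd ``sweep_noise_rel`` is applied to all
    three channels.
    """
    if spec.logG_storage_slope >= 0 or spec.logG_loss_slope >= 0:
        raise GenerationError("modulus slopes must be negative (melt softens)")
    if spec.logG_storage_slope >= spec.logG_loss_slope:
        raise GenerationError(
            "storage modulus must fall faster than loss modulus for a "
            "unique crossover")
    if spec.t_eta_lower_C <= spec.t_eta_upper_C:
        raise GenerationError(
            "eta* must reach 10^4 Pa.s below the 10^3 Pa.s temperature")

    lo, hi = spec.sweep_range_C
    T_C = np.arange(lo, hi + 0.5 * spec.sweep_step_C, spec.sweep_step_C)
    eta_slope = -1.0 / (spec.t_eta_lower_C - spec.t_eta_upper_C)
    log_eta = 4.0 + eta_slope * (T_C - spec.t_eta_upper_C)
    log_gc = math.log10(spec.g_crossover)
    log_gp = log_gc + spec.logG_storage_slope * (T_C - spec.crossover_C)
    log_gpp = log_gc + spec.logG_loss_slope * (T_C - spec.crossover_C)

    eta = 10.0 ** log_eta
    gp = 10.0 ** log_gp
    gpp = 10.0 ** log_gpp
    if spec.sweep_noise_rel > 0:
        rng = _rng(spec, stream=3)
        eta = eta * np.exp(rng.normal(0, spec.sweep_noise_rel, eta.shape))
        gp = gp * np.exp(rng.normal(0, spec.sweep_noise_rel, gp.shape))
        gpp = gpp * np.exp(rng.normal(0, spec.sweep_noise_rel, gpp.shape))
    return OscillatorySweep(
        T=celsius_to_kelvin(T_C), G_storage=gp, G_loss=gpp, eta_star=eta,
        frequency=0.1,
    )
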