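"""Processing-temperature windows from oscillatory temperature sweeps.

Hot-melt extrusion wants the melt's complex viscosity η* (at low angular
frequency, 0.1 rad·s⁻¹) inside roughly 1000-10,000 Pa·s, and processing
above the viscoelastic crossover G′ = G″ (tan δ = 1) where the melt is
predominantly viscous.  This module reads a temperature sweep of G′, G″
and η* and emits the rule-based extrusion range and printing temperature.

Oscillatory sweeps probe low shear rates; shear-thinning cellulose ethers
can in practice be processed below the window predicted here, so the
returned window always carries a machine-readable shear-sensitivity
caveat rather than attempting a shear-rate correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, celsius_to_kelvin

#: Extrudability band for complex viscosity at 0.1 rad/s, Pa·s.
ETA_UPPER = 1.0e4
ETA_LOWER = 1.0e3


@dataclass
class OscillatorySweep:
    """One oscillatory temperature sweep at fixed frequency and strain.

    Temperatures in K, strictly increasing; moduli in Pa and complex
    viscosity in Pa·s, all strictly positive.
    """

    T: np.ndarray
    G_storage: np.ndarray
    G_loss: np.ndarray
    eta_star: np.ndarray
    frequency: float = 0.1  # rad/s
    strain: float = 1.0     # %

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.G_storage = np.asarray(self.G_storage, dtype=float)
        self.G_loss = np.asarray(self.G_loss, dtype=float)
        self.eta_star = np.asarray(self.eta_star, dtype=float)
        n = len(self.T)
        if not (len(self.G_storage) == len(self.G_loss)
                == len(self.eta_star) == n):
            raise ValueError("sweep columns must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        for name in ("G_storage", "G_loss", "eta_star"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ProcessingWindow:
    """Rule-based extrusion range and printing temperature, in K.

    Fields are ``None`` where the sweep never crosses the corresponding
    threshold.  ``shear_sensitivity_caveat`` marks that the true window of
    shear-thinning polymers may sit below the oscillatory prediction.
    """

    extrusion_low: Optional[float]
    extrusion_high: Optional[float]
    printing_T: Optional[float]
    crossover_T: Optional[float]
    shear_sensitivity_caveat: bool = True

    def __post_init__(self) -> None:
        if (self.extrusion_low is not None and self.extrusion_high is not None
                and self.extrusion_low > self.extrusion_high):
            raise ValueError("extrusion_low must not exceed extrusion_high")


def loss_tangent(sweep: OscillatorySweep) -> np.ndarray:
    """Per-sample loss tangent tan δ = G″/G′."""
    return sweep.G_loss / sweep.G_storage


def _interp_crossing(T: np.ndarray, values: np.ndarray,
                     i: int) -> float:
    """Linear interpolation of the zero crossing of ``values`` in [i, i+1]."""
    v0, v1 = values[i], values[i + 1]
    if v0 == v1:
        return float(T[i])
    return float(T[i] + (T[i + 1] - T[i]) * v0 / (v0 - v1))


def crossover_temperature(sweep: OscillatorySweep) -> Optional[float]:
    """Temperature (K) of the viscoelastic crossover G′ = G″, if any.

    Found as the sign change of log G′ − log G″, refined by linear
    interpolation in (T, log modulus) — the natural space for quantities
    spanning decades.  Returns ``None`` when no crossing exists; with
    multiple crossings the lowest-temperature one is returned and a
    multiplicity warning is emitted.
    """
    diff = np.log(sweep.G_storage) - np.log(sweep.G_loss)
    signs = np.sign(diff)
    crossings = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    exact = np.nonzero(diff == 0)[0]
    candidates: List[float] = [float(sweep.T[i]) for i in exact]
    candidates += [_interp_crossing(sweep.T, diff, int(i)) for i in crossings]
    if not candidates:
        return None
    if len(candidates) > 1:
        warnings.warn(
            f"{len(candidates)} G'=G'' crossings found; returning the lowest")
    return min(candidates)


def viscosity_threshold_temperature(
    sweep: OscillatorySweep, threshold: float,
) -> Optional[float]:
    """Temperature (K) where η* first falls through ``threshold``.

    Interpolated linearly in (T, log η*).  ``None`` if the sweep never
    crosses the threshold from above; a non-monotone η* near the threshold
    yields the first falling crossing with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = np.log(sweep.eta_star) - math.log(threshold)
    falling = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    if len(falling) == 0:
        return None
    if len(falling) > 1:
        warnings.warn(
            f"eta* crosses {threshold:g} Pa.s {len(falling)} times "
            f"(non-monotone sweep); returning the first crossing")
    return _interp_crossing(sweep.T, diff, int(falling[0]))


def _round_down_5C(t_kelvin: float) -> float:
    """Round a temperature down to the nearest 5 °C grid point, in K."""
    t_c = t_kelvin - CELSIUS_OFFSET
    return 5.0 * math.floor(t_c / 5.0 + 1e-9) + CELSIUS_OFFSET


def processing_window(
    sweep: OscillatorySweep,
    *,
    printing_rule: str = "crossover_floor_5C",
    shear_sensitivity_caveat: bool = True,
) -> ProcessingWindow:
    """Derive the extrusion range and printing temperature from a sweep.

    The extrusion range spans the temperatures at which η* passes
    10,000 Pa·s (lower bound) and 1000 Pa·s (upper bound).  The printing
    temperature follows ``printing_rule``:

    * ``"crossover_floor_5C"`` (default) — the G′ = G″ crossover rounded
      down to the nearest 5 °C;
    * ``"crossover"`` — the crossover itself.

    Missing crossings leave the corresponding fields ``None`` rather than
    raising: a partial window is still informative.
    """
    t_upper = viscosity_threshold_temperature(sweep, ETA_UPPER)
    t_lower = viscosity_threshold_temperature(sweep, ETA_LOWER)
    t_cross = crossover_temperature(sweep)
    if printing_rule == "crossover_floor_5C":
        printing = None if t_cross is None else _round_down_5C(t_cross)
    elif printing_rule == "crossover":
        printing = t_cross
    else:
        raise ValueError(f"unknown printing rule {printing_rule!r}")
    return ProcessingWindow(
        extrusion_low=t_upper,
        extrusion_high=t_lower,
        printing_T=printing,
        crossover_T=t_cross,
        shear_sensitivity_caveat=shear_sensitivity_caveat,
    )


# --- CSV I/O ----------------------------------------------------------------

def read_sweep_csv(path: str | Path, *, frequency: float = 0.1,
                   strain: float = 1.0) -> OscillatorySweep:
    """Read a sweep CSV with columns ``T, unit, G_storage, G_loss, eta_star``."""
    df = pd.read_csv(path)
    required = {"T", "unit", "G_storage", "G_loss", "eta_star"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    T = df["T"].to_numpy(dtype=float)
    celsius = df["unit"].astype(str).str.upper().eq("C").to_numpy()
    T = np.where(celsius, celsius_to_kelvin(T), T)
    return OscillatorySweep(
        T=T,
        G_storage=df["G_storage"].to_numpy(dtype=float),
        G_loss=df["G_loss"].to_numpy(dtype=float),
        eta_star=df["eta_star"].to_numpy(dtype=float),
        frequency=frequency, strain=strain,
    )


def write_sweep_csv(sweep: OscillatorySweep, path: str | Path) -> None:
    """Write a sweep in the CSV dialect read_sweep_csv accepts (Kelvin)."""
    pd.DataFrame({
        "T": sweep.T, "unit": "K",
        "G_storage": sweep.G_storage,
        "G_loss": sweep.G_loss,
        "eta_star": sweep.eta_star,
    }).to_csv(path, index=False)


def window_to_dict(window: ProcessingWindow) -> dict:
    """JSON-serialisable report of a processing window (K and °C)."""
    def pair(t: Optional[float]) -> Optional[dict]:
        if t is None:
            return None
        return {"K": t, "C": t - CELSIUS_OFFSET}

    return {
        "extrusion_low": pair(window.extrusion_low),
        "extrusion_high": pair(window.extrusion_high),
        "printing_T": pair(window.printing_T),
        "crossover_T": pair(window.crossover_T),
        "eta_band_Pa_s": [ETA_LOWER, ETA_UPPER],
        "shear_sensitivity_caveat": window.shear_sensitivity_caveat,
    }
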