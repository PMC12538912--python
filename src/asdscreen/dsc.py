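"""Melting-endset extraction from DSC thermograms.

The depressed melting point of a drug-rich mixture is read as the *endset*
of its melting endotherm: the temperature at which the endothermic trace
returns to the instrument baseline after melting.  The detector fits a
straight baseline over a post-melting window, finds the endotherm peak,
walks the trailing edge and interpolates the exact baseline crossing.
A set of endsets across compositions assembles into the depression dataset
the interaction-parameter regression consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .components import Component
from .constants import celsius_to_kelvin
from .thermo import MeltingDepressionDataset


class NoMeltingEventError(ValueError):
    """No endotherm rises above the noise floor of the trace."""


@dataclass
class Thermogram:
    """A single heating trace: temperature vs heat flow.

    Heat flow is stored endotherm-positive; set ``exo_up=True`` on input if
    the instrument recorded exothermic events upward and the trace will be
    sign-flipped on construction.  Models the second heating cycle, after
    moisture release.
    """

    T: np.ndarray
    heat_flow: np.ndarray
    composition: Optional[float] = None
    scan_rate: float = 10.0
    exo_up: bool = False

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.T.shape != self.heat_flow.shape:
            raise ValueError("T and heat_flow must have equal length")
        if len(self.T) < 50:
            raise ValueError(
                f"need >= 50 samples for endset detection, got {len(self.T)}")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.exo_up:
            self.heat_flow = -self.heat_flow
            self.exo_up = False


@dataclass(frozen=True)
class EndsetResult:
    """Detected melting endset with the fitted baseline and peak position."""

    T_endset: float
    baseline: Tuple[float, float]  # (slope, intercept) of heat_flow vs T
    peak_T: float
    flags: Tuple[str, ...] = ()


# Trailing-edge samples are considered back on baseline once their excess
# drops inside this multiple of the baseline-residual RMS; in the noise-free
# limit the band collapses and the rule reduces to the geometric
# intersection of trace and baseline.
_BAND_RMS_MULTIPLE = 3.0
# Peak must exceed this multiple of the residual RMS to count as a melting
# event at all.
_PEAK_RMS_MULTIPLE = 6.0


def detect_endset(
    thermogram: Thermogram,
    baseline_window: Tuple[float, float],
) -> EndsetResult:
    """Locate the melting endset of a thermogram.

    Parameters
    ----------
    thermogram:
        Endotherm-positive heating trace.
    baseline_window:
        (T_low, T_high) in K, a region *after* the melting event over which
        the instrument baseline is fitted as a straight line.

    Returns
    -------
    EndsetResult with the first trailing-edge temperature at which the
    trace re-enters a tolerance band around the fitted baseline, refined
    by linear interpolation to the exact band crossing.  Deterministic for
    a fixed input.

    Raises
    ------
    NoMeltingEventError
        If no peak rises above the noise floor.
    ValueError
        If the baseline window lies outside the scan or contains the peak.
    """
    T, hf = thermogram.T, thermogram.heat_flow
    lo, hi = baseline_window
    in_window = (T >= lo) & (T <= hi)
    if in_window.sum() < 5:
        raise ValueError(
            f"baseline window {baseline_window} covers "
            f"{int(in_window.sum())} samples; need >= 5")

    # locate the endotherm on a whole-trace detrend first: insensitive to
    # any affine baseline and to a badly placed window
    coarse = np.polyval(np.polyfit(T, hf, 1), T)
    coarse_excess = hf - coarse
    # point-to-point noise floor; successive differences of the (smooth)
    # trace are noise-dominated
    diffs = np.diff(hf)
    noise_sigma = float(1.4826 * np.median(np.abs(diffs - np.median(diffs)))
                        / math.sqrt(2.0))
    coarse_peak = int(np.argmax(coarse_excess))
    if coarse_excess[coarse_peak] <= max(_PEAK_RMS_MULTIPLE * noise_sigma,
                                         1e-12):
        raise NoMeltingEventError(
            "no melting event: trace never rises above the noise floor")
    if lo <= float(T[coarse_peak]) <= hi:
        raise ValueError(
            f"baseline window {baseline_window} overlaps the endotherm peak "
            f"at {float(T[coarse_peak]):.2f} K")

    slope, intercept = np.polyfit(T[in_window], hf[in_window], 1)
    baseline = slope * T + intercept
    excess = hf - baseline
    rms = float(np.sqrt(np.mean(excess[in_window] ** 2)))
    peak_idx = int(np.argmax(excess))
    peak_height = float(excess[peak_idx])
    peak_T = float(T[peak_idx])

    band = max(_BAND_RMS_MULTIPLE * rms, 1e-9 * peak_height)
    flags: List[str] = []
    trailing = np.nonzero((excess <= band) & (np.arange(len(T)) > peak_idx))[0]
    if len(trailing) == 0:
        raise ValueError("trace never returns to baseline after the peak")
    i = int(trailing[0])
    # interpolate the crossing of the band edge between samples i-1 and i
    e0, e1 = excess[i - 1], excess[i]
    if e0 == e1:
        t_endset = float(T[i])
    else:
        frac = (e0 - band) / (e0 - e1)
        t_endset = float(T[i - 1] + frac * (T[i] - T[i - 1]))
    if rms > 0.02 * peak_height:
        flags.append("noisy_baseline")
    return EndsetResult(T_endset=t_endset,
                        baseline=(float(slope), float(intercept)),
                        peak_T=peak_T, flags=tuple(flags))


def assemble_depression_dataset(
    results: Sequence[Tuple[float, EndsetResult]],
    drug: Component,
) -> MeltingDepressionDataset:
    """Collect per-composition endsets into a depression dataset.

    Endsets above the pure drug's melting point (apparent elevation —
    typically a detection artefact) are excluded and recorded in the
    provenance string; at least three compositions must survive.
    """
    drug.require("Tm_pure")
    if len(results) < 3:
        raise ValueError(f"need >= 3 compositions, got {len(results)}")
    kept: List[Tuple[float, float]] = []
    excluded: List[str] = []
    scan_rates = set()
    for w, res in sorted(results, key=lambda r: r[0]):
        if res.T_endset > drug.Tm_pure:
            excluded.append(
                f"w={w:.3f}: endset {res.T_endset:.2f} K > Tm_pure "
                f"{drug.Tm_pure:.2f} K")
            continue
        kept.append((w, res.T_endset))
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} points survive exclusion; need >= 3 "
            f"(excluded: {excluded})")
    provenance = "DSC endset extraction"
    if excluded:
        provenance += "; excluded [" + "; ".join(excluded) + "]"
    dataset = MeltingDepressionDataset(points=kept, provenance=provenance)
    dataset.validate(Tm_pure=drug.Tm_pure)
    return dataset


# --- CSV I/O ----------------------------------------------------------------

def read_thermogram_csv(path: str | Path, *, composition: float | None = None,
                        scan_rate: float = 10.0) -> Thermogram:
    """Read a thermogram CSV with columns ``T, heat_flow, unit, exo_up``.

    ``unit`` is C or K per row; ``exo_up`` is 0/1 and must be constant
    within a file.
    """
    df = pd.read_csv(path)
    required = {"T", "heat_flow", "unit", "exo_up"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    T = df["T"].to_numpy(dtype=float)
    celsius = df["unit"].astype(str).str.upper().eq("C").to_numpy()
    T = np.where(celsius, celsius_to_kelvin(T), T)
    exo_flags = set(df["exo_up"].astype(int))
    if len(exo_flags) != 1:
        raise ValueError(f"{path}: exo_up must be constant within a file")
    return Thermogram(T=T, heat_flow=df["heat_flow"].to_numpy(dtype=float),
                      composition=composition, scan_rate=scan_rate,
                      exo_up=bool(exo_flags.pop()))


def write_thermogram_csv(thermogram: Thermogram, path: str | Path) -> None:
    """Write a thermogram in the CSV dialect read_thermogram_csv accepts."""
    df = pd.DataFrame({
        "T": thermogram.T,
        "heat_flow": thermogram.heat_flow,
        "unit": "K",
        "exo_up": 0,
    })
    df.to_csv(path, index=False)


def read_depression_csv(path: str | Path) -> MeltingDepressionDataset:
    """Read a depression table CSV with columns ``w_drug, Tm_mix, unit``."""
    df = pd.read_csv(path)
    required = {"w_drug", "Tm_mix", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tm = df["Tm_mix"].to_numpy(dtype=float)
    celsius = df["unit"].astype(str).str.upper().eq("C").to_numpy()
    tm = np.where(celsius, celsius_to_kelvin(tm), tm)
    points = list(zip(df["w_drug"].astype(float), tm.astype(float)))
    return MeltingDepressionDataset(points=points, provenance=str(path))


def write_depression_csv(dataset: MeltingDepressionDataset,
                         path: str | Path) -> None:
    """Write a depression dataset as ``w_drug, Tm_mix, unit`` rows (Kelvin)."""
    df = pd.DataFrame(dataset.points, columns=["w_drug", "Tm_mix"])
    df["unit"] = "K"
    df.to_csv(path, index=False)
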