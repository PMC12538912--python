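"""End-to-end screening pipeline and report bundle.

Runs the full pre-screening chain — endset extraction (or a supplied
depression table), the χ regression, the Hansen-parameter χ at ambient
temperature, the χ(T) fit, phase-diagram construction, state-point
classification, and the rheology processing window — and writes a JSON
report bundle.  Alongside the computed values the bundle restates the
published reference values for the felodipine-HPMC system so a reader can
compare the two columns at a glance.

Also houses the UV drug-content utility: a straight-line absorbance
calibration inverted for concentration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import dsc, rheology, thermo
from .components import (BinaryMixture, felodipine_hpmc, load_mixture,
                         state_point)
from .constants import kelvin_to_celsius
from .simulate import SyntheticSpec, simulate_melting_depression, simulate_sweep


# --- UV calibration ----------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """Linear UV calibration A = slope·C + intercept.

    Defaults are the validated felodipine line (slope 0.017 absorbance per
    µg·mL⁻¹, intercept 0.0057).
    """

    slope: float = 0.017
    intercept: float = 0.0057

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")


def concentration_from_absorbance(
    absorbance: float,
    line: CalibrationLine = CalibrationLine(),
    expected_concentration: Optional[float] = None,
) -> Tuple[float, Optional[float]]:
    """Invert the calibration line: C = (A − intercept)/slope.

    Returns ``(concentration, drug_content_percent)``; the percentage is
    measured/expected × 100 and ``None`` when no expectation is given.
    """
    conc = (absorbance - line.intercept) / line.slope
    percent = None
    if expected_concentration is not None:
        if expected_concentration <= 0:
            raise ValueError("expected concentration must be positive")
        percent = conc / expected_concentration * 100.0
    return conc, percent


# --- pipeline ----------------------------------------------------------------

#: Published reference values for the felodipine / Affinisol HPMC system,
#: restated next to the computed values in the report bundle.
REFERENCE_VALUES = {
    "chi_25C": 4.11,
    "chi_at_Tm": 0.441,
    "abs_A": 8.88,
    "B": 3872.16,
}

#: Canonical anchor temperatures (K) for the χ(T) fit: ambient is taken as
#: 298 K exactly, the high anchor is the drug's melting point.
AMBIENT_ANCHOR_T = 298.0


@dataclass
class RunConfig:
    """Inputs and defaults for one pipeline run.

    Paths may be ``None``: a missing depression table falls back to the
    synthetic generator (seeded), missing thermograms fall back to the
    depression table, and a missing sweep simply leaves the processing
    window absent from the bundle.
    """

    out_dir: Path
    mixture_path: Optional[Path] = None
    depression_csv: Optional[Path] = None
    thermogram_manifest: Optional[Path] = None
    sweep_csv: Optional[Path] = None
    m: Optional[float] = None
    seed: int = 0
    state_points: Sequence[Tuple[float, float]] = (
        (0.10, 318.15),  # 10 % w/w at the stressed storage temperature 45 °C
        (0.30, 318.15),
    )

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _load_mixture(config: RunConfig) -> BinaryMixture:
    if config.mixture_path is not None:
        mixture = load_mixture(config.mixture_path)
        if config.m is not None:
            mixture = BinaryMixture(drug=mixture.drug,
                                    polymer=mixture.polymer, m=config.m)
        return mixture
    return felodipine_hpmc(m=config.m if config.m is not None else 100.0)


def _depression_dataset(config: RunConfig, mixture: BinaryMixture):
    if config.thermogram_manifest is not None:
        import pandas as pd
        manifest = pd.read_csv(config.thermogram_manifest)
        root = Path(config.thermogram_manifest).parent
        results = []
        for _, row in manifest.iterrows():
            tg = dsc.read_thermogram_csv(root / str(row["path"]),
                                         composition=float(row["w_drug"]))
            window = (float(row["baseline_lo"]), float(row["baseline_hi"]))
            results.append((float(row["w_drug"]),
                            dsc.detect_endset(tg, window)))
        return dsc.assemble_depression_dataset(results, mixture.drug)
    if config.depression_csv is not None:
        return dsc.read_depression_csv(config.depression_csv)
    spec = SyntheticSpec(m=mixture.m, seed=config.seed)
    return simulate_melting_depression(spec, mixture)


def _write_if_changed(path: Path, text: str) -> None:
    # re-running an unchanged stage leaves its output untouched
    if path.exists() and path.read_text() == text:
        return
    path.write_text(text)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute every pipeline stage and write the report bundle.

    Returns the bundle as a dict; files written under ``config.out_dir``:
    ``phase_diagram.json``, ``processing_window.json`` (when a sweep is
    available) and ``report.json``.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    mixture = _load_mixture(config)
    drug, polymer = mixture.drug, mixture.polymer
    stages: List[str] = []

    # 1. melting-point depression -> chi at the drug's melting point
    dataset = _depression_dataset(config, mixture)
    transformed = thermo.depression_transform(dataset, mixture)
    fit = thermo.fit_chi_at_tm(transformed)
    stages.append("depression_fit")

    # 2. Hansen-parameter chi at ambient temperature
    chi_ambient = thermo.chi_from_hsp(drug, polymer, AMBIENT_ANCHOR_T)
    stages.append("hsp_chi")

    # 3. chi(T) = A + B/T through the two computed anchors
    model = thermo.fit_chi_temperature_model([
        (AMBIENT_ANCHOR_T, chi_ambient),
        (drug.Tm_pure, fit.chi_at_tm),
    ])
    stages.append("chi_temperature_fit")

    # 4. phase diagram
    diagram = thermo.build_phase_diagram(model, mixture)
    diagram.to_json(config.out_dir / "phase_diagram.json")
    stages.append("phase_diagram")

    # 5. state-point classification
    classifications = []
    for w, T in config.state_points:
        point = state_point(mixture, T, w_drug=w)
        label = diagram.classify(point)
        classifications.append({
            "w_drug": w, "T_K": T, "T_C": kelvin_to_celsius(T),
            "phi_drug": point.phi_drug,
            "stability": label.stability,
            "glass_relation": label.glass_relation,
            "region_code": label.region_code,
        })
    stages.append("classification")

    # 6. rheology window (optional stage)
    window_dict = None
    if config.sweep_csv is not None:
        sweep = rheology.read_sweep_csv(config.sweep_csv)
        window = rheology.processing_window(sweep)
        window_dict = rheology.window_to_dict(window)
        _write_if_changed(config.out_dir / "processing_window.json",
                          json.dumps(window_dict, indent=2))
        stages.append("rheology_window")

    computed = {
        "chi_25C": chi_ambient,
        "chi_at_Tm": fit.chi_at_tm,
        "abs_A": abs(model.A),
        "B": model.B,
    }
    bundle = {
        "schema_version": 1,
        "seed": config.seed,
        "mixture": {"drug": drug.name, "polymer": polymer.name,
                    "m": mixture.m},
        "depression_fit": {
            "chi_at_tm": fit.chi_at_tm,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "provenance": dataset.provenance,
        },
        "chi_model": {"A": model.A, "B": model.B,
                      "anchors": [list(a) for a in model.anchors]},
        "classifications": classifications,
        "processing_window": window_dict,
        "reference_comparison": [
            {"quantity": key,
             "reference": REFERENCE_VALUES[key],
             "computed": computed[key]}
            for key in REFERENCE_VALUES
        ],
        "stages_run": stages,
    }
    _write_if_changed(config.out_dir / "report.json",
                      json.dumps(bundle, indent=2))
    return bundle
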