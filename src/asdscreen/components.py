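"""Chemical components, binary drug-polymer mixtures, and fraction conversions.

A :class:`Component` is one species (a small-molecule drug or a polymer)
carrying the thermal, volumetric, and Hansen-solubility-parameter properties
the thermodynamic model needs.  A :class:`BinaryMixture` pairs a crystalline
drug with an amorphous polymer and fixes the molar-volume ratio ``m`` that
enters the Flory-Huggins lattice model.

Compositions are reported by formulators as weight fractions but the lattice
model works in volume fractions; the conversion through the two densities is
implemented here once and reused everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


class ConfigurationError(ValueError):
    """A component or mixture is missing a property an operation requires."""


@dataclass(frozen=True)
class Component:
    """One chemical species with the properties used by the screening model.

    Parameters
    ----------
    name:
        Human-readable identifier.
    molar_mass:
        g·mol⁻¹.
    density:
        g·cm⁻³ (amorphous/bulk density used for weight-to-volume conversion).
    Tm_pure:
        Melting point of the pure crystalline solid, K.  Only meaningful for
        the drug; ``None`` for fully amorphous polymers.
    dH_fus_per_mass:
        Specific enthalpy of fusion, J·g⁻¹ (drug only).
    Tg:
        Glass-transition temperature, K.
    molar_volume:
        cm³·mol⁻¹.  If omitted it is derived as ``molar_mass / density``.
    hsp:
        Hansen solubility parameter triple (dispersion, polar,
        hydrogen-bonding), each in (J·cm⁻³)^½.
    """

    name: str
    molar_mass: Optional[float] = None
    density: Optional[float] = None
    Tm_pure: Optional[float] = None
    dH_fus_per_mass: Optional[float] = None
    Tg: Optional[float] = None
    molar_volume: Optional[float] = None
    hsp: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        for attr in ("molar_mass", "density", "Tm_pure", "dH_fus_per_mass",
                     "Tg", "molar_volume"):
            value = getattr(self, attr)
            if value is not None and value <= 0:
                raise ConfigurationError(
                    f"{self.name}: {attr} must be strictly positive, got {value}")
        if self.hsp is not None:
            if len(self.hsp) != 3:
                raise ConfigurationError(
                    f"{self.name}: hsp must be a (dispersion, polar, "
                    f"hydrogen-bonding) triple")
            object.__setattr__(self, "hsp", tuple(float(x) for x in self.hsp))
        if (self.molar_volume is None and self.molar_mass is not None
                and self.density is not None):
            object.__setattr__(self, "molar_volume",
                               self.molar_mass / self.density)
        if (self.Tm_pure is not None and self.Tg is not None
                and self.Tm_pure <= self.Tg):
            raise ConfigurationError(
                f"{self.name}: Tm_pure ({self.Tm_pure} K) must exceed "
                f"Tg ({self.Tg} K) for a crystalline glass-former")

    @property
    def dH_fus_molar(self) -> float:
        """Molar enthalpy of fusion, J·mol⁻¹.

        The melting-point-depression equation balances the fusion enthalpy
        against R in J·mol⁻¹·K⁻¹, so the per-mass value supplied by DSC is
        converted through the molar mass.
        """
        if self.dH_fus_per_mass is None or self.molar_mass is None:
            raise ConfigurationError(
                f"{self.name}: dH_fus_per_mass and molar_mass are required "
                f"to form the molar enthalpy of fusion")
        return self.dH_fus_per_mass * self.molar_mass

    def require(self, *attrs: str) -> None:
        """Raise :class:`ConfigurationError` naming any missing attribute."""
        for attr in attrs:
            if getattr(self, attr) is None:
                raise ConfigurationError(
                    f"component '{self.name}' is missing '{attr}'")


@dataclass(frozen=True)
class BinaryMixture:
    """A drug-polymer pair with the molar-volume ratio of the lattice model.

    ``m`` is the ratio of polymer to drug molar volume; for a polymer
    dissolving a small molecule it is at least 1 and typically large.
    Both densities must be present so weight and volume fractions are
    interconvertible.
    """

    drug: Component
    polymer: Component
    m: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError(
                f"molar-volume ratio m must be >= 1 for a polymer-small-"
                f"molecule pair, got {self.m}")
        self.drug.require("density")
        self.polymer.require("density")

    def volume_fraction_from_weight(self, w_drug: float) -> float:
        """Drug volume fraction φ from drug weight fraction w.

        φ = (w/ρ_d) / (w/ρ_d + (1−w)/ρ_p).
        """
        if not 0.0 <= w_drug <= 1.0:
            raise ValueError(f"weight fraction must lie in [0, 1], got {w_drug}")
        v_drug = w_drug / self.drug.density
        v_poly = (1.0 - w_drug) / self.polymer.density
        return v_drug / (v_drug + v_poly)

    def weight_fraction_from_volume(self, phi_drug: float) -> float:
        """Inverse of :meth:`volume_fraction_from_weight`."""
        if not 0.0 <= phi_drug <= 1.0:
            raise ValueError(f"volume fraction must lie in [0, 1], got {phi_drug}")
        m_drug = phi_drug * self.drug.density
        m_poly = (1.0 - phi_drug) * self.polymer.density
        return m_drug / (m_drug + m_poly)


@dataclass(frozen=True)
class StatePoint:
    """A (composition, temperature) point on the phase diagram.

    Weight and volume fraction are stored together and must be consistent
    under the mixture's densities; use :func:`state_point` to build one from
    either fraction.
    """

    w_drug: float
    phi_drug: float
    T: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_drug <= 1.0:
            raise ValueError(f"w_drug out of [0, 1]: {self.w_drug}")
        if not 0.0 <= self.phi_drug <= 1.0:
            raise ValueError(f"phi_drug out of [0, 1]: {self.phi_drug}")
        if self.T <= 0:
            raise ValueError(f"temperature must be positive (K): {self.T}")


def state_point(mixture: BinaryMixture, T: float, *,
                w_drug: Optional[float] = None,
                phi_drug: Optional[float] = None) -> StatePoint:
    """Build a :class:`StatePoint` from either a weight or a volume fraction."""
    if (w_drug is None) == (phi_drug is None):
        raise ValueError("specify exactly one of w_drug, phi_drug")
    if w_drug is not None:
        phi_drug = mixture.volume_fraction_from_weight(w_drug)
    else:
        w_drug = mixture.weight_fraction_from_volume(phi_drug)
    return StatePoint(w_drug=w_drug, phi_drug=phi_drug, T=T)


# --- Reference parameterisation: felodipine in Affinisol HPMC HME 15LV ------
#
# Felodipine is the model crystalline glass-former: Tm 415.25 K, specific
# fusion enthalpy 84.55 J/g, Tg 317.55 K, Hansen triple (18.0, 11.9, 12.3).
# The HPMC carrier is amorphous with Tg 364.67 K and Hansen triple
# (22.4, 5.2, 8.4).  The molar volume of felodipine (296 cm³/mol, from a
# molar mass of 384.26 g/mol at a density of 1.30 g/cm³), both densities,
# and the chain-length ratio m = 100 are defaults a caller can override.

def felodipine() -> Component:
    """Reference drug component: felodipine."""
    return Component(
        name="felodipine",
        molar_mass=384.26,
        density=1.30,
        Tm_pure=415.25,
        dH_fus_per_mass=84.55,
        Tg=317.55,
        molar_volume=296.0,
        hsp=(18.0, 11.9, 12.3),
    )


def hpmc_affinisol() -> Component:
    """Reference polymer component: Affinisol HPMC HME 15LV."""
    return Component(
        name="hpmc-affinisol-15lv",
        density=1.20,
        Tg=364.67,
        hsp=(22.4, 5.2, 8.4),
    )


def felodipine_hpmc(m: float = 100.0) -> BinaryMixture:
    """Reference felodipine / Affinisol HPMC mixture with chain ratio ``m``."""
    return BinaryMixture(drug=felodipine(), polymer=hpmc_affinisol(), m=m)


# --- YAML configuration -----------------------------------------------------

def _component_from_dict(d: dict) -> Component:
    hsp = d.get("hsp")
    if hsp is not None:
        hsp = tuple(float(x) for x in hsp)
    return Component(
        name=d["name"],
        molar_mass=d.get("molar_mass"),
        density=d.get("density"),
        Tm_pure=d.get("Tm_pure"),
        dH_fus_per_mass=d.get("dH_fus_per_mass"),
        Tg=d.get("Tg"),
        molar_volume=d.get("molar_volume"),
        hsp=hsp,
    )


def load_mixture(path: str | Path) -> BinaryMixture:
    """Load a drug-polymer mixture from a YAML configuration file.

    The file carries ``drug:`` and ``polymer:`` mappings mirroring the
    :class:`Component` fields plus a top-level ``m:`` ratio.  All
    temperatures in the file are Kelvin.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        drug = _component_from_dict(cfg["drug"])
        polymer = _component_from_dict(cfg["polymer"])
        m = float(cfg.get("m", 100.0))
    except KeyError as exc:
        raise ConfigurationError(f"mixture config missing section {exc}") from exc
    return BinaryMixture(drug=drug, polymer=polymer, m=m)
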