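"""Physical constants used throughout the package.

The gas constant is fixed here and deliberately not user-configurable:
every equation in the thermodynamic core balances energies against R·T,
so letting a caller override R would silently break unit contracts.
"""

#: Molar gas constant, J·mol⁻¹·K⁻¹.
R = 8.314

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from °C to K."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature from K to °C."""
    return t_kelvin - CELSIUS_OFFSET
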