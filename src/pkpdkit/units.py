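"""Mass/molar concentration conversion."""

from __future__ import annotations

from .exceptions import InputError

#: cimicoxib molar mass, g/mol
DEFAULT_MOLAR_MASS = 381.81


def convert_mass_molar(
    value: float, molar_mass: float = DEFAULT_MOLAR_MASS, direction: str = "mass_to_molar"
) -> float:
    """Convert ng/mL <-> nmol/mL.

    ``mass_to_molar`` divides by the molar mass (g/mol == ng/nmol);
    ``molar_to_mass`` multiplies.  No rounding is applied here.
    """
    if molar_mass <= 0:
        raise InputError("molar mass must be positive")
    if value < 0:
        raise InputError("value must be non-negative")
    if direction == "mass_to_molar":
        return value / molar_mass
    if direction == "molar_to_mass":
        return value * molar_mass
    raise InputError("direction must be 'mass_to_molar' or 'molar_to_mass'")
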