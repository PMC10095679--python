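"""Package-wide unit conventions.

Length angstrom, time ps, energy kcal/mol, mass amu, temperature K.
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2 (4.184 kJ/mol / 10).
KCAL_PER_MOL_TO_AKMA = 0.4184


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
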