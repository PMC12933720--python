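"""Physical constants and unit conventions.

The package works in GROMACS-style units throughout:
length nm, time ps, energy kJ/mol, mass amu, temperature K.
With these units 1 amu nm^2/ps^2 = 1 kJ/mol, so kinetic energy needs
no conversion factor.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.00831446

#: kJ per kcal
KJ_PER_KCAL = 4.184


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
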