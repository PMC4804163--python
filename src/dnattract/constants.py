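"""Physical constants and unit conversions used across the package.

Internal units: distance in angstrom (A), energy in kcal/mol, time in
seconds unless a name says otherwise.
"""

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3

#: Simulation temperature (K) used throughout the free-energy stack.
T_DEFAULT = 300.0

#: k_B T at 300 K, kcal/mol
KBT_300 = KB_KCAL * T_DEFAULT

#: thermochemical calorie: kJ per kcal
KJ_PER_KCAL = 4.184

#: umbrella force constant 2,000 kJ mol^-1 nm^-2 expressed in kcal mol^-1 A^-2
#: (1 kcal = 4.184 kJ, 1 nm^2 = 100 A^2)
K_UMBRELLA_KCAL = 2000.0 / (KJ_PER_KCAL * 100.0)


def kbt(temperature_k: float = T_DEFAULT) -> float:
    """k_B T in kcal/mol at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL * temperature_k
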