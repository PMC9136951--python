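"""Physical constants and project-wide unit conventions.

Units everywhere: lengths in Å, energies in kJ/mol, temperatures in K,
charges in elementary charge units.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083144626

#: Coulomb constant k_e = 1/(4 pi eps0), kJ mol^-1 Å e^-2.
COULOMB = 138.935458

#: Hard-core sentinel: site pairs closer than this (Å) short-circuit to +inf.
HARD_CORE_DIST = 1e-6


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
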