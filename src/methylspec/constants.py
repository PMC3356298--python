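"""Physical constants and global unit conventions.

Units are fixed package-wide: lengths in Å, energies in kcal/mol, angles
in degrees, temperature in K.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 1.987204259e-3

#: Simulation temperature of the study conditions, K
DEFAULT_TEMPERATURE = 283.15


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol for a temperature in K."""
    if temperature <= 0:
        from .errors import ParameterError

        raise ParameterError(f"temperature must be > 0 K, got {temperature}")
    return KB * temperature
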