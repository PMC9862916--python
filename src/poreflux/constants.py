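"""Physical constants and package-wide unit conventions.

Internal units everywhere: Ångström for length, nanosecond for time,
k_B·T for energy (kcal/mol on output), Kelvin for temperature.  The +z
direction points toward the extracellular side.
"""

# Molar gas constant, 8.314 J mol^-1 K^-1, expressed in kcal (1 kcal = 4184 J).
GAS_CONSTANT_KCAL = 8.314 / 4184.0  # kcal mol^-1 K^-1

# Volume of a single water molecule used to convert the collective diffusion
# coefficient D_n (s^-1) into an osmotic permeability pf (cm^3 s^-1).
V_WATER_CM3 = 3.0e-23  # cm^3

# Coulomb constant e^2/(4*pi*eps0) in kcal mol^-1 Å e^-2.
COULOMB_KCAL_A = 332.0637

DEFAULT_TEMPERATURE = 310.15  # K


def kT_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature."""
    return GAS_CONSTANT_KCAL * temperature


class PorefluxError(ValueError):
    """Raised for invalid inputs or unsupported formats."""
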