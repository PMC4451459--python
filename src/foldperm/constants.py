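"""Physical constants and reference conditions.

All free energies are in kcal/mol, denaturant concentrations in M,
rate constants in s^-1, temperatures in K.
"""

#: Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

#: Default experimental temperature, K (25 degrees C)
T_DEFAULT = 298.15

#: RT at the default temperature, kcal/mol
RT_DEFAULT = R_KCAL * T_DEFAULT  # 0.59248


def rt(temperature_K: float = T_DEFAULT) -> float:
    """RT in kcal/mol at the given absolute temperature."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return R_KCAL * temperature_K
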