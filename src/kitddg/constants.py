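"""Physical constants and unit conventions.

All energies in the package are kJ/mol, temperatures in kelvin, distances in
nanometres, angles in degrees unless a function says otherwise.
"""

#: Boltzmann constant expressed per mole, kJ/(mol*K).
KB_KJ_PER_MOL_K: float = 0.008314463


def beta_from_temperature(temperature: float) -> float:
    """Inverse thermal energy beta = 1/(k_B*T) in mol/kJ.

    Raises ValueError for non-positive temperature.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return 1.0 / (KB_KJ_PER_MOL_K * temperature)
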