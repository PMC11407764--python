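"""Physical constants (CODATA 2018) shared across modules."""

#: Avogadro constant, 1/mol
N_A = 6.02214076e23

#: Faraday constant, C/mol
FARADAY = 96485.33212

#: Molar gas constant, J/(mol K)
R_GAS = 8.314462618


def thermal_voltage_mV(temperature_K: float) -> float:
    """RT/F in millivolts at the given absolute temperature."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (K)")
    return 1000.0 * R_GAS * temperature_K / FARADAY
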