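"""Physical constants shared across the package.

All energies are kJ/mol; potentials cross into mV only at the Nernst
boundary in :mod:`dsbredox.redox`.
"""

#: Boltzmann constant, kJ/(mol K)
KB_KJ_MOL_K: float = 0.0083145

#: Faraday constant, kJ/(mol V)
FARADAY_KJ_MOL_V: float = 96.485

#: Default simulation temperature, K
DEFAULT_TEMPERATURE_K: float = 300.0


def beta(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KJ_MOL_K * temperature)
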