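"""Physical constants (CODATA) and the water reference composition.

All stopping-power and CT-number results in the package are normalized to
liquid water at 1 g/cm^3; its two-element composition is pinned here so that
the normalization is structural rather than tabulated.
"""

# CODATA 2018
ELECTRON_REST_ENERGY_EV = 510_998.95  # m_e c^2
PROTON_REST_ENERGY_MEV = 938.272_088_16  # m_p c^2
AVOGADRO = 6.022_140_76e23  # 1/mol

#: Mass fractions of liquid water.
WATER_MASS_FRACTIONS = {"H": 0.111_894, "O": 0.888_106}
WATER_DENSITY = 1.0  # g/cm^3

#: Default proton beam kinetic energy used throughout (MeV).
DEFAULT_BEAM_ENERGY_MEV = 100.0


def beta_squared(kinetic_energy_mev: float) -> float:
    """Relativistic beta^2 of a proton with the given kinetic energy."""
    gamma = 1.0 + kinetic_energy_mev / PROTON_REST_ENERGY_MEV
    return 1.0 - 1.0 / (gamma * gamma)
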