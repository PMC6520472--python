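"""Physical constants and the single flux unit-conversion factor.

All chamber fluxes are carried in nmol N2O m-2 s-1; all cumulative
emissions and model-side emission rates in kg N ha-1 (day-1).  The
bridge between the two scales is :data:`NMOL_M2_S_TO_KGN_HA_DAY`.
"""

#: molar mass of nitrogen, g mol-1
N_MOLAR_MASS_G = 14.0067

#: universal gas constant, J mol-1 K-1
R_GAS = 8.314

SECONDS_PER_DAY = 86400.0
M2_PER_HA = 1.0e4

#: kg N ha-1 day-1 emitted per 1 nmol N2O m-2 s-1 of sustained flux.
#: Each mole of N2O carries two moles of N.
NMOL_M2_S_TO_KGN_HA_DAY = (
    2.0 * N_MOLAR_MASS_G * 1.0e-9 * SECONDS_PER_DAY * M2_PER_HA / 1.0e3
)


def air_molar_density(temperature_k: float, pressure_pa: float = 101325.0) -> float:
    """Ideal-gas molar density of air in mol m-3."""
    if temperature_k <= 0 or pressure_pa <= 0:
        raise ValueError("temperature and pressure must be positive")
    return pressure_pa / (R_GAS * temperature_k)
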