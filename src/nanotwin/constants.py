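"""Physical constants and common fluid properties (SI units)."""

R_GAS = 8.314462618  # universal gas constant, J mol^-1 K^-1
K_BOLTZMANN = 1.380649e-23  # J K^-1
N_AVOGADRO = 6.02214076e23  # mol^-1

ANGSTROM = 1e-10  # m

# Water / air properties used by the spray-drying balances.
LATENT_HEAT_WATER = 2.26e6  # J kg^-1, latent heat of vaporization near 100 degC
CP_WATER_LIQ = 4186.0  # J kg^-1 K^-1
CP_WATER_VAP = 1900.0  # J kg^-1 K^-1
CP_AIR_DRY = 1006.0  # J kg^-1 K^-1
MW_WATER = 18.015e-3  # kg mol^-1
MW_AIR = 28.965e-3  # kg mol^-1
P_ATM = 101325.0  # Pa

# Molarity of pure water, used in the surface-tension correlation
# gamma = -0.33 kB T (NA rho / Mr)^(2/3) [ln(S0 / 55.6) + 5].
WATER_MOLARITY = 55.6  # mol L^-1
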