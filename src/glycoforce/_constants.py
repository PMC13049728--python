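"""Physical constants and unit conversion factors.

Internal unit system: length nm, force pN, pressure Pa, temperature K,
spring constant N/m (= 1000 pN/nm at the force/deflection interface).
Converters live at the I/O boundary; everything inside the package works
in these units.
"""

# Boltzmann constant in pN*nm/K (1.380649e-23 J/K; 1 J = 1e21 pN*nm)
BOLTZMANN_PN_NM = 1.380649e-2

# 1 Pa = 1 N/m^2 = 1e-6 pN/nm^2
PA_TO_PN_PER_NM2 = 1.0e-6

# 1 N/m = 1000 pN/nm
N_PER_M_TO_PN_PER_NM = 1.0e3

# 1 um = 1000 nm
UM_TO_NM = 1.0e3

# Acquisition temperature used throughout (36.2 degC)
DEFAULT_TEMPERATURE_K = 309.35
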