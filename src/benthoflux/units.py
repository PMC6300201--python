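"""Unit conversion constants used at reporting boundaries.

Internal conventions
--------------------
* diffusivities: cm^2 s^-1
* concentrations: umol L^-1 (== mmol m^-3)
* chamber fluxes: slope in umol L^-1 h^-1 times V[L]/A[m^2] -> mmol m^-2 d^-1
* microprofile gradients: umol L^-1 mm^-1 (== mol m^-4)
* pore-water gradients: umol L^-1 cm^-1 (== 0.1 mol m^-4)
* fluxes: mmol m^-2 d^-1, signed, positive = efflux (sediment to water)
"""

SECONDS_PER_DAY = 86_400.0
HOURS_PER_DAY = 24.0

#: (umol L^-1 h^-1) * L / m^2  ->  mmol m^-2 d^-1
CHAMBER_SLOPE_TO_FLUX = HOURS_PER_DAY / 1000.0  # 0.024

#: D[cm^2 s^-1] * g[umol L^-1 mm^-1] -> mmol m^-2 d^-1
#: 1 umol/L/mm = 1 mol m^-4; 1 cm^2/s = 1e-4 m^2/s; * 86400 s/d * 1e3 mmol/mol
MICRO_GRADIENT_TO_FLUX = 1e-4 * SECONDS_PER_DAY * 1e3  # 8640

#: D[cm^2 s^-1] * g[umol L^-1 cm^-1] -> mmol m^-2 d^-1
PORE_GRADIENT_TO_FLUX = MICRO_GRADIENT_TO_FLUX / 10.0  # 864

#: mg C -> mmol C uses the carbon molar mass (g mol^-1); default chosen so that
#: the conversion of a production rate printed in mg C m^-2 d^-1 reproduces the
#: conventional 1-decimal mmol values (12.0, not 12.011).
DEFAULT_CARBON_MOLAR_MASS = 12.0

#: Redfield molar ratio used to express oxygen uptake as carbon equivalents.
REDFIELD_C_TO_O2 = 106.0 / 138.0
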