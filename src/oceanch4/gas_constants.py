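"""Published coefficient tables for gas-exchange calculations.

Every empirical fit used by :mod:`oceanch4.gasex` lives here so the
parameterizations can be inspected or swapped without touching code.

Sources
-------
* Schmidt-number quartics in seawater (t in degC, valid -2..40 degC):
  Wanninkhof (2014), Limnol. Oceanogr. Methods 12, Table 1.
* CH4 solubility in seawater (equilibrium concentration from a dry
  atmospheric mole fraction): Wiesenburg & Guinasso (1979), J. Chem. Eng.
  Data 24 — coefficients for concentration in nmol l-1.
* CO2 solubility K_H (mol l-1 atm-1): Weiss (1974), Mar. Chem. 2.
"""

# Sc(t) = a + b*t + c*t**2 + d*t**3 + e*t**4, t in degC (seawater, S=35)
SCHMIDT_COEFFS: dict[str, tuple[float, float, float, float, float]] = {
    "CO2": (2116.8, -136.25, 4.7353, -0.092307, 7.555e-4),
    "CH4": (2101.2, -131.54, 4.4931, -0.08676, 7.0663e-4),
}

#: Reference Schmidt number (CO2 in seawater at 20 degC) used to normalize
#: the quadratic wind-speed transfer-velocity relationship.
SC_REFERENCE = 660.0

# ln C = ln(x_gas) + A1 + A2*(100/T) + A3*ln(T/100) + A4*(T/100)
#        + S * (B1 + B2*(T/100) + B3*(T/100)**2)
# T in Kelvin, S practical salinity, x_gas the dry-air mole fraction
# (dimensionless), C in nmol l-1.
CH4_SOLUBILITY_COEFFS = {
    "A1": -415.2807,
    "A2": 596.8104,
    "A3": 379.2599,
    "A4": -62.0757,
    "B1": -0.059160,
    "B2": 0.032174,
    "B3": -0.0048198,
}

# ln K_H = A1 + A2*(100/T) + A3*ln(T/100)
#          + S * (B1 + B2*(T/100) + B3*(T/100)**2)
# T in Kelvin; K_H in mol l-1 atm-1.
CO2_KH_COEFFS = {
    "A1": -58.0931,
    "A2": 90.5069,
    "A3": 22.2940,
    "B1": 0.027766,
    "B2": -0.025888,
    "B3": 0.0050578,
}

#: Hours per year (365.25 d) used for per-hour -> per-year flux conversion.
HOURS_PER_YEAR = 8766.0
DAYS_PER_YEAR = 365.25
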