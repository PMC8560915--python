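"""Physical constants and unit conversions used across the package.

All hydrodynamic arithmetic is done in CGS units (cm, g, s, erg), which is
the convention of the analytical-ultracentrifugation literature: the gas
constant is in erg mol^-1 K^-1, viscosity in poise, and sedimentation
coefficients internally in seconds (1 Svedberg = 1e-13 s).
"""

# CGS gas constant, erg mol^-1 K^-1
R_GAS = 8.314462618e7

# Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

# 1 Svedberg in seconds
SVEDBERG = 1e-13

# Water at 20 degrees C (used only as Svedberg-relation defaults; no
# s20,w buffer correction is applied anywhere in the package)
WATER_DENSITY_20C = 0.99823       # g/mL
WATER_VISCOSITY_20C = 0.010016    # poise (= 1.0016 cP)

# Mass spectrometry constants (monoisotopic, Da)
PROTON_MASS = 1.007276
# mass difference between deuterium and protium
DEUTERIUM_DELTA = 1.0062767

# Convenient defaults for globular proteins
DEFAULT_VBAR = 0.73   # mL/g
DEFAULT_FF0 = 1.4     # frictional ratio


def rpm_to_omega(rpm: float) -> float:
    """Angular velocity (rad/s) from rotor speed in revolutions per minute."""
    import math

    return rpm * 2.0 * math.pi / 60.0
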