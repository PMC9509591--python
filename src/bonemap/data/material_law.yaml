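# Default density -> Young's modulus material law.
#
# Lotz linear conversion: rho_app [g/cm3] = lotz_slope * rho_CT [mg/cm3] + lotz_intercept
# Branches: rho_app <= 0 -> air_modulus
#           0 < rho_app <= cutoff_density -> trab_coefficient * rho_app**trab_exponent
#           rho_app > cutoff_density -> cortical_modulus
# trab_coefficient already includes the transverse-stiffness factor
# (8920 * 1.28 = 11417.6).
lotz_slope: 0.0012        # g/cm3 per mg/cm3
lotz_intercept: 0.17      # g/cm3
air_modulus: 1.0          # MPa
trab_coefficient: 11417.6 # MPa per (g/cm3)^trab_exponent
trab_exponent: 1.89
transverse_factor: 1.28
cortical_modulus: 17000.0 # MPa
cutoff_density: 1.0       # g/cm3 (user-settable trabecular/cortical cutoff)
modulus_floor: 1.0        # MPa lower clamp on the trabecular branch; 0 disables
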