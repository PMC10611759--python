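"""Physical constants used throughout the energetics modules.

All free energies in this package are expressed in kcal/mol, temperatures
in kelvin, and rate constants in 1/s.
"""

#: Universal gas constant, kcal/(K*mol) (1.986 cal/(K*mol)).
R_KCAL = 1.986e-3

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Planck constant, J*s.
H_PLANCK = 6.62607e-34

#: 37 degrees Celsius in kelvin, the physiological reference temperature.
T_37C = 310.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15
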