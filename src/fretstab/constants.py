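"""Physical constants and unit helpers (kcal/mol, K internally)."""

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425e-3

#: Default reference temperature for reporting unfolding free energies (K).
T_REF_DEFAULT = 298.15

#: Default simulation/estimation temperature for work values (K).
T_WORK_DEFAULT = 300.0

ZERO_CELSIUS = 273.15


def celsius_to_kelvin(t_c):
    return t_c + ZERO_CELSIUS


def kelvin_to_celsius(t_k):
    return t_k - ZERO_CELSIUS
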