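"""Physical constants in the unit system used throughout (kcal, mol, K, s)."""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 0.0019872

#: Boltzmann constant over Planck constant, s^-1 K^-1 (k_B/h).
KB_OVER_H = 2.083661912e10

#: Default thermodynamic temperature, K.
T_DEFAULT = 298.15


def kbt_over_h(temperature: float = T_DEFAULT) -> float:
    """Eyring prefactor k_B*T/h in s^-1 (6.212e12 at 298.15 K)."""
    return KB_OVER_H * temperature
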