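"""Physical constants in the MD unit system (kJ/mol, nm, ps, K, degrees)."""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA, GROMACS convention).
KB = 0.008314462618

#: Electric conversion factor e^2/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB_FACTOR = 138.935458

#: Default simulation temperature, K.
T_DEFAULT = 300.0


def kbt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB * temperature
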