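"""Physical constants and unit conventions.

Two unit modes are used throughout:

* ``physical`` — kcal/mol for energies, Å for lengths, ps for times,
  K for temperatures.  ``kT = K_B_KCAL * T``.
* ``reduced`` — kT = 1 exactly, unit length, unit friction, unit mass.
  All closed-form oracle tests run in this mode.
"""

K_B_KCAL = 0.0019872041
"""Boltzmann constant in kcal/mol/K."""

K_B_SI = 1.380649e-23
"""Boltzmann constant in J/K (exact, SI)."""

H_SI = 6.62607015e-34
"""Planck constant in J·s (exact, SI)."""

R_KCAL = 1.98720425864083e-3
"""Molar gas constant in kcal/mol/K."""


def thermal_energy(temperature: float, units_mode: str = "physical") -> float:
    """kT in the energy unit of the given mode.

    In reduced mode the temperature argument is a multiplier of the unit
    temperature, so ``thermal_energy(1.0, "reduced") == 1.0``.
    """
    if units_mode == "reduced":
        return float(temperature)
    if units_mode == "physical":
        return K_B_KCAL * float(temperature)
    raise ValueError(f"unknown units_mode: {units_mode!r}")
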