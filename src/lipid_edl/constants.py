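"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system: lengths in nm, energies in units of k_B*T, electrostatic
potential as the reduced potential psi = e*Psi/(k_B*T), number densities in
nm^-3, charges as charge numbers (units of e). Conversions to volts, C/m^2 and
mol/dm^3 happen only at the I/O boundary.
"""

import math

ELEMENTARY_CHARGE = 1.602176634e-19
"""Elementary charge e in C."""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant k_B in J/K."""

VACUUM_PERMITTIVITY = 8.8541878128e-12
"""Vacuum permittivity eps_0 in F/m."""

AVOGADRO = 6.02214076e23
"""Avogadro constant in 1/mol."""

NM = 1e-9
"""One nanometre in metres."""

MOLAR_TO_NM3 = AVOGADRO / 1e24
"""mol/dm^3 -> number density in nm^-3 (0.602214076)."""

NM3_TO_MOLAR = 1.0 / MOLAR_TO_NM3

FOUR_PI = 4.0 * math.pi
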