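"""Physical constants and material parameters used across the package.

The iron-oxide cores are treated as magnetite for the purpose of converting
an iron mass into a magnetic core volume; the exact stoichiometry only sets
an overall scale of the simulated moments and cancels out of every
calibration-based quantity.
"""

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Molar mass of iron, kg/mol.
M_FE = 55.845e-3

#: Mass density of magnetite (Fe3O4), kg/m^3.
MAGNETITE_DENSITY = 5170.0

#: Iron mass fraction of magnetite, 3*M(Fe)/M(Fe3O4).
MAGNETITE_FE_FRACTION = 3 * 55.845 / 231.533

#: Nominal device limit of detection for the third-harmonic moment, A m^2.
LOD_NOMINAL = 2.0e-11
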