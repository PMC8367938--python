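"""Physical constants and unit conversions.

Internal working units for trajectory data are Angstrom, kJ mol^-1 A^-1
(forces), amu and ps, the native units of GROMACS-style trajectories.
Covariance matrices and frequencies are evaluated in per-particle SI so
that eigenvalues divided by k_B*T have units of s^-2 and map directly to
vibrational frequencies. Entropies are molar (J K^-1 mol^-1); free
energies are reported in kcal mol^-1.
"""

from scipy import constants as _c

#: molar gas constant, J K^-1 mol^-1
R = _c.R
#: Boltzmann constant, J K^-1 (per particle)
KB = _c.k
#: Planck constant, J s
H = _c.h
#: Avogadro constant, mol^-1
N_A = _c.N_A

#: atomic mass unit -> kg
AMU_TO_KG = _c.atomic_mass
#: Angstrom -> m
ANGSTROM_TO_M = 1e-10
#: kJ mol^-1 -> J (per particle)
KJMOL_TO_J = 1e3 / N_A
#: force, kJ mol^-1 A^-1 -> N (per particle)
FORCE_TO_SI = KJMOL_TO_J / ANGSTROM_TO_M
#: torque, kJ mol^-1 rad^-1 -> J rad^-1 (per particle)
TORQUE_TO_SI = KJMOL_TO_J
#: moment of inertia, amu A^2 -> kg m^2
INERTIA_TO_SI = AMU_TO_KG * ANGSTROM_TO_M**2
#: force constant, kJ mol^-1 A^-2 -> N m^-1 (per particle)
FORCE_CONSTANT_TO_SI = KJMOL_TO_J / ANGSTROM_TO_M**2

#: thermochemical kcal -> J
KCAL_TO_J = _c.calorie * 1e3
#: J mol^-1 -> kcal mol^-1
JMOL_TO_KCALMOL = 1.0 / KCAL_TO_J
#: kJ mol^-1 -> kcal mol^-1
KJMOL_TO_KCALMOL = 1e3 / KCAL_TO_J

#: standard-state mole fraction of a 1 M aqueous solute (one solute per
#: 55.5 waters in the 1661 A^3 standard volume)
X_AQ_STANDARD = 1.0 / 55.5
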