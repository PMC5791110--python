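"""Physical constants and per-element parameter tables.

All distances are in Å, energies in kcal/mol, charges in elementary units.
"""

from __future__ import annotations

# Coulomb conversion: q1*q2/d [e^2/Å] -> kcal/mol
COULOMB_KCAL = 332.0637

# Bondi van der Waals radii (Å). Elements outside the table fall back to 1.70 Å.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "He": 1.40,
    "Ne": 1.54,
    "Ar": 1.88,
    "Na": 2.27,
    "K": 2.75,
}
DEFAULT_VDW_RADIUS = 1.70

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Br": 79.904,
    "I": 126.904,
}

# UFF Lennard-Jones parameters per element: (x_vdw Å = position of the
# minimum, D kcal/mol = well depth).  sigma = x / 2^(1/6).
_UFF_X_D = {
    "H": (2.886, 0.044),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "F": (3.364, 0.050),
    "P": (4.147, 0.305),
    "S": (4.035, 0.274),
    "Cl": (3.947, 0.227),
    "Br": (4.189, 0.251),
    "I": (4.50, 0.339),
}

_SIXTH_ROOT_OF_TWO = 2.0 ** (1.0 / 6.0)

UFF_SIGMA = {el: x / _SIXTH_ROOT_OF_TWO for el, (x, d) in _UFF_X_D.items()}
UFF_EPSILON = {el: d for el, (x, d) in _UFF_X_D.items()}

# Acid-base reference values used by the protonation model.
PKA_CARBOXYL = 4.7
PKA_HYDROXYL = 10.6

# Charge convention for protons added/removed by (de)protonation.
HYDROXYL_H_CHARGE = 0.40
CARBOXYL_H_CHARGE = 0.45

# Idealized sp3 geometry for the PVA chain builder.
CC_BOND = 1.54
CO_BOND = 1.43
OH_BOND = 0.96
CH_BOND = 1.09
TETRAHEDRAL_ANGLE_DEG = 109.471
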