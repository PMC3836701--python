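"""Physical constants and unit conventions.

The package works in a kcal/mol - Angstrom - picosecond - Kelvin - Dalton
unit system (the convention of most coarse-grained protein MD codes).
Charges are in units of the elementary charge e.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872

#: Coulomb constant e^2/(4 pi eps0), kcal*Angstrom/(mol*e^2)
COULOMB_K = 332.0636

#: conversion: 1 kcal/mol = 418.4 Da*A^2/ps^2 (so a = F * ACC_FACTOR / m)
KCAL_TO_DA_A2_PS2 = 418.4

#: default mass per residue bead, Da (average amino-acid residue mass)
RESIDUE_MASS = 110.0

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: formal charge per residue type when explicit charges are enabled;
#: His is treated as neutral.
RESIDUE_CHARGES = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}

ZINC_CHARGE = 2.0
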