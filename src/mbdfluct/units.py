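"""Unit conversion constants.

All internal quantities are in Hartree atomic units (Bohr, Hartree); file
formats use their conventional units (XYZ in Angstrom, cube in Bohr) and
reports print both Hartree and kcal/mol.
"""

BOHR_RADIUS_ANGSTROM = 0.52917721067
ANGSTROM_TO_BOHR = 1.0 / BOHR_RADIUS_ANGSTROM
BOHR_TO_ANGSTROM = BOHR_RADIUS_ANGSTROM

HARTREE_TO_KCALMOL = 627.509
HARTREE_TO_EV = 27.211386
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
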