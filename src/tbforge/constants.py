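"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units; conversions are applied
only at I/O boundaries (Angstrom / eV / kcal/mol).
"""

HARTREE_TO_EV = 27.211386245988
HARTREE_TO_KCALMOL = 627.509474
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
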