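"""Unit conventions and conversion factors.

All internal quantities are in Hartree atomic units (hbar = 1, lengths in
Bohr, energies in Hartree, polarizabilities in Bohr^3, angular frequencies
in Hartree/hbar).  User-facing reports convert on output only.
"""

#: hbar in atomic units (kept symbolic so formulas read like the theory).
HBAR = 1.0

#: 1 Angstrom in Bohr.
ANGSTROM_TO_BOHR = 1.8897259886

#: 1 Hartree in eV (CODATA 2018).
HARTREE_TO_EV = 27.211386245988

#: 1 atomic unit of electric dipole (e*a0) in Debye.
AU_TO_DEBYE = 2.5417464519

BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR
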