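"""Physical constants and unit conversions (CODATA-style values)."""

#: Bohr radius in Angstrom; all internal coordinates are bohr, XYZ files are A.
BOHR_TO_ANGSTROM = 0.52917721092
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Boltzmann constant in hartree / K.
KB_HARTREE = 3.166811563e-6

#: Hartree to electron volt.
HARTREE_TO_EV = 27.211386245988

#: Wolfsberg-Helmholz proportionality constant for off-diagonal EHT elements.
WOLFSBERG_HELMHOLZ_K = 1.75
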