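"""Physical constants and unit conversions.

All internal geometry is in bohr, densities in e/bohr^3 and potentials in
hartree/e; conversion to kcal/mol happens exactly once, at the surface-
descriptor stage.
"""

#: hartree -> kcal/mol (CODATA)
HARTREE_TO_KCAL_PER_MOL: float = 627.5095

#: 1 angstrom in bohr
BOHR_PER_ANGSTROM: float = 1.0 / 0.529177210903

#: Bader convention: molecular surface = 0.001 e/bohr^3 density contour
DEFAULT_ISOVALUE: float = 0.001
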