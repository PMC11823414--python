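"""Unit constants.

All internal quantities are in Hartree atomic units (hartree, bohr,
atomic time); trajectory files use Å and femtoseconds.
"""

#: 1 Å in bohr.
ANGSTROM_TO_BOHR = 1.8897261246

#: 1 bohr in Å.
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

#: 1 atomic time unit in femtoseconds.
AU_TIME_IN_FS = 0.02418884254

#: Boltzmann constant in hartree per kelvin.
KB_HARTREE_PER_K = 3.166811563e-6


def fs_to_au(t_fs: float) -> float:
    """Convert a time from femtoseconds to atomic units."""
    return t_fs / AU_TIME_IN_FS
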