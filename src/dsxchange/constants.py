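"""Physical constants and unit conversions.

The package works in GROMACS-style units: lengths in nm, energies in
kJ/mol, times in ps, temperatures in K.  External pulling forces are
specified in pN (the AFM/force-clamp convention) and converted to
kJ/mol/nm internally.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.008314462618

#: 1 pN·nm expressed in kJ/mol (multiply a force in pN by this to get kJ/mol/nm).
PN_TO_KJ_PER_MOL_NM = 0.6022140857


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kJ/mol for a temperature in K."""
    return KB * temperature


def pn_to_internal(force_pn: float) -> float:
    """Convert a force in pN to kJ/mol/nm."""
    return force_pn * PN_TO_KJ_PER_MOL_NM
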