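"""Unit conventions and physical constants.

Internal units everywhere in this package: Angstrom, kcal/mol, electron
charges, radians.  kJ/mol appears only at reporting time (tables in the
molecular-modelling literature are usually printed in kJ/mol).
"""

#: Coulomb's constant in kcal*Angstrom/(mol*e^2), the convention used by the
#: AMBER family of force fields.
COULOMB_CONSTANT = 332.0522

#: AMBER prmtop files store charges multiplied by this factor
#: (sqrt(COULOMB_CONSTANT), historically 18.2223).
PRMTOP_CHARGE_SCALE = 18.2223

#: Conversion factor for reporting.
KCAL_PER_MOL_TO_KJ_PER_MOL = 4.184

#: Default 1-4 scale divisors for the AMBER/GAFF force-field family, applied
#: when a topology file does not state its own.
DEFAULT_SCEE = 1.2
DEFAULT_SCNB = 2.0
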