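"""Monoisotopic mass constants for peptide fragment arithmetic.

All masses are in Dalton. The residue table covers the 20 standard amino
acids only; non-standard codes (U, O, B, Z, X) are deliberately absent so
that peptides outside the training alphabet fail fast at parse time.
"""

from types import MappingProxyType

#: Monoisotopic residue masses (Da), standard 20 amino acids.
RESIDUE_MASSES = MappingProxyType(
    {
        "G": 57.02146372057,
        "A": 71.03711378471,
        "S": 87.03202840427,
        "P": 97.05276384885,
        "V": 99.06841391299,
        "T": 101.04767846841,
        "C": 103.00918478471,
        "L": 113.08406397713,
        "I": 113.08406397713,
        "N": 114.04292744114,
        "D": 115.02694302383,
        "Q": 128.05857750528,
        "K": 128.09496301399,
        "E": 129.04259308797,
        "M": 131.04048491299,
        "H": 137.05891185845,
        "F": 147.06841391299,
        "R": 156.10111102359,
        "Y": 163.06332853255,
        "W": 186.07931294985,
    }
)

#: Mass of a proton (Da); used for charging, not the hydrogen atom mass.
PROTON = 1.00727646688

#: Monoisotopic mass of water (Da); the H-/-OH default termini together.
WATER = 18.0105646863

#: The 20 standard one-letter residue codes, alphabetically.
STANDARD_RESIDUES = tuple(sorted(RESIDUE_MASSES))
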