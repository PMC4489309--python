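"""Independent oracles: direct summation from a published residue table.

These deliberately do not import the package's mass or encoding machinery;
they recompute fragment masses by naive summation so that agreement with
the implementation is a two-route check.
"""

# Monoisotopic residue masses (Da), standard published values.
RESIDUES = {
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
WATER = 18.0105646863
PROTON = 1.00727646688


def naive_peptide_mass(seq, mod_shifts=(), nterm_shift=0.0, cterm_shift=0.0):
    """Neutral mass by direct summation; `mod_shifts` is any iterable of Da."""
    return (
        sum(RESIDUES[aa] for aa in seq)
        + WATER
        + sum(mod_shifts)
        + nterm_shift
        + cterm_shift
    )


def naive_fragment_mz(
    seq,
    series,
    index,
    ion_charge,
    mods=None,
    nterm_shift=0.0,
    cterm_shift=0.0,
):
    """m/z by direct summation. `mods` maps 1-based position -> Da shift."""
    mods = mods or {}
    L = len(seq)
    if series == "b":
        neutral = sum(RESIDUES[aa] for aa in seq[:index]) + nterm_shift
        neutral += sum(shift for pos, shift in mods.items() if pos <= index)
    elif series == "y":
        neutral = sum(RESIDUES[aa] for aa in seq[L - index:]) + WATER + cterm_shift
        neutral += sum(shift for pos, shift in mods.items() if pos > L - index)
    else:
        raise ValueError(series)
    return (neutral + ion_charge * PROTON) / ion_charge
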