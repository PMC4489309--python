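"""Theoretical b/y fragment-ion m/z computation.

Only the four series the models predict are generated: b+, y+, b++, y++.
The b ion with index i holds residues 1..i (plus any N-terminal and
in-range modification shifts); the y ion with index i holds the last i
residues plus water (plus C-terminal and in-range shifts). m/z follows the
standard convention (neutral + z * proton) / z with the proton mass, using
monoisotopic residue masses throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .constants import PROTON, RESIDUE_MASSES, WATER
from .peptides import Peptide, terminal_shift
from .ptms import PTMRegistry

#: The predicted (series, ion charge) combinations, in canonical order.
ION_SERIES: tuple[tuple[str, int], ...] = (("b", 1), ("y", 1), ("b", 2), ("y", 2))


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical (optionally intensity-carrying) fragment ion."""

    series: str  # 'b' or 'y'
    ion_charge: int  # 1 or 2
    index: int  # 1 .. L-1
    mz: float
    intensity: float | None = None

    @property
    def label(self) -> str:
        """Conventional label, e.g. ``b3+`` or ``y5++``."""
        return f"{self.series}{self.index}{'+' * self.ion_charge}"


def _neutral_fragment_mass(
    p: Peptide, registry: PTMRegistry, series: str, index: int
) -> float:
    length = len(p)
    if not 1 <= index <= length - 1:
        raise ValueError(f"fragment index {index} outside [1, {length - 1}]")
    if series == "b":
        mass = sum(RESIDUE_MASSES[aa] for aa in p.sequence[:index])
        mass += terminal_shift(p, registry, n=True)
        mass += sum(
            registry.get(sym).mass_shift
            for pos, sym in p.residue_mods.items()
            if pos <= index
        )
    elif series == "y":
        mass = sum(RESIDUE_MASSES[aa] for aa in p.sequence[length - index :]) + WATER
        mass += terminal_shift(p, registry, n=False)
        mass += sum(
            registry.get(sym).mass_shift
            for pos, sym in p.residue_mods.items()
            if pos > length - index
        )
    else:
        raise ValueError(f"unknown ion series {series!r}; expected 'b' or 'y'")
    return mass


def fragment_mz(
    p: Peptide,
    registry: PTMRegistry,
    series: str,
    index: int,
    ion_charge: int,
) -> float:
    """m/z (Th) of the `series` ion with `index` at `ion_charge` (1 or 2)."""
    if ion_charge not in (1, 2):
        raise ValueError(f"ion charge must be 1 or 2, got {ion_charge}")
    neutral = _neutral_fragment_mass(p, registry, series, index)
    return (neutral + ion_charge * PROTON) / ion_charge


def iter_fragments(p: Peptide, registry: PTMRegistry) -> Iterator[FragmentIon]:
    """All 4 x (L-1) fragment ions in (series, index) order, unsorted."""
    for series, z in ION_SERIES:
        for index in range(1, len(p)):
            yield FragmentIon(series, z, index, fragment_mz(p, registry, series, index, z))


def theoretical_spectrum(p: Peptide, registry: PTMRegistry) -> list[FragmentIon]:
    """All four series at indices 1..L-1, sorted ascending by m/z."""
    return sorted(iter_fragments(p, registry), key=lambda ion: ion.mz)
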