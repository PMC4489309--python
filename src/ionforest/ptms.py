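"""Post-translational modification definitions and the local registry.

A PTM is identified in peptide strings by a lowercase symbol. Internal
(residue) symbols contain no dash; N-terminal symbols end with ``-`` (e.g.
``ace-``) and C-terminal symbols start with ``-`` (e.g. ``-am``), mirroring
the dash position in the ``H-P-OH`` peptide grammar. Mass shifts are given
numerically (monoisotopic Da); no online database is queried.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .constants import STANDARD_RESIDUES

#: Markers used in a definition's residue scope for terminal modifications.
N_TERM_MARKER = "n-term"
C_TERM_MARKER = "c-term"

#: Server-style cap on distinct PTM symbols per run.
MAX_PTMS = 8


class PTMError(ValueError):
    """Invalid PTM definition, unregistered symbol, or scope violation."""


@dataclass(frozen=True)
class PTMDefinition:
    """One modification: symbol, human-readable name, mass shift, scope.

    Parameters
    ----------
    symbol
        Lowercase identifier as written in peptide strings. ``ace-`` is
        N-terminal, ``-am`` is C-terminal, ``ox`` is internal.
    name
        Free-text name (e.g. ``Oxidation``).
    mass_shift
        Monoisotopic mass shift in Da (may be negative).
    residues
        For internal symbols: the 1-letter residue codes the PTM may
        annotate. For terminal symbols: ``{"n-term"}`` or ``{"c-term"}``.
    """

    symbol: str
    name: str
    mass_shift: float
    residues: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sym = self.symbol
        if not sym:
            raise PTMError("PTM symbol must be nonempty")
        core = sym.strip("-")
        if not core or not core.islower() or not core.isalpha():
            raise PTMError(f"PTM symbol {sym!r} must be lowercase letters")
        if self.is_n_term and self.is_c_term:
            raise PTMError(f"PTM symbol {sym!r} cannot be both terminal kinds")
        if not (self.is_n_term or self.is_c_term) and "-" in sym:
            raise PTMError(f"internal PTM symbol {sym!r} may not contain '-'")
        if not (self.mass_shift == self.mass_shift and abs(self.mass_shift) < 1e6):
            raise PTMError(f"mass shift of {sym!r} is not finite")
        scope = frozenset(self.residues)
        if self.is_n_term:
            expected = {N_TERM_MARKER}
        elif self.is_c_term:
            expected = {C_TERM_MARKER}
        else:
            expected = None
        if expected is not None:
            if scope and scope != expected:
                raise PTMError(
                    f"terminal PTM {sym!r} scope must be {expected}, got {set(scope)}"
                )
            scope = frozenset(expected)
        else:
            bad = scope - set(STANDARD_RESIDUES)
            if bad:
                raise PTMError(f"PTM {sym!r} scope has non-standard residues {sorted(bad)}")
            if not scope:
                raise PTMError(f"internal PTM {sym!r} needs at least one residue")
        object.__setattr__(self, "residues", scope)

    @property
    def is_n_term(self) -> bool:
        return self.symbol.endswith("-")

    @property
    def is_c_term(self) -> bool:
        return self.symbol.startswith("-")

    @property
    def is_internal(self) -> bool:
        return not (self.is_n_term or self.is_c_term)

    def allows(self, residue: str) -> bool:
        """Whether this (internal) PTM may sit on `residue`."""
        return residue in self.residues


class PTMRegistry:
    """Collection of :class:`PTMDefinition` keyed by symbol.

    Enforces unique symbols and the per-run cap of :data:`MAX_PTMS`
    distinct symbols unless ``allow_excess=True``.
    """

    def __init__(
        self,
        definitions: Iterable[PTMDefinition] = (),
        *,
        allow_excess: bool = False,
    ) -> None:
        self._defs: dict[str, PTMDefinition] = {}
        self._allow_excess = allow_excess
        for d in definitions:
            self.add(d)

    def add(self, definition: PTMDefinition) -> None:
        if definition.symbol in self._defs:
            raise PTMError(f"duplicate PTM symbol {definition.symbol!r}")
        if not self._allow_excess and len(self._defs) >= MAX_PTMS:
            raise PTMError(
                f"registry holds {len(self._defs)} PTMs; at most {MAX_PTMS} "
                "symbols are supported per run (pass allow_excess=True to override)"
            )
        self._defs[definition.symbol] = definition

    def get(self, symbol: str) -> PTMDefinition:
        try:
            return self._defs[symbol]
        except KeyError:
            raise PTMError(f"unregistered symbol {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._defs

    def __iter__(self) -> Iterator[PTMDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self._defs)

    def internal_symbols(self) -> tuple[str, ...]:
        return tuple(s for s, d in self._defs.items() if d.is_internal)


def load_ptm_table(path: str | Path, *, allow_excess: bool = False) -> PTMRegistry:
    """Load a registry from a CSV table.

    Columns: ``symbol,name,mass_shift,residues`` where ``residues`` is a
    comma-free ``;``-free string of 1-letter codes (e.g. ``STY``) or the
    marker ``n-term``/``c-term``.
    """
    defs = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            scope_raw = row["residues"].strip()
            if scope_raw in (N_TERM_MARKER, C_TERM_MARKER):
                scope: frozenset[str] = frozenset({scope_raw})
            else:
                scope = frozenset(scope_raw)
            defs.append(
                PTMDefinition(
                    symbol=row["symbol"].strip(),
                    name=row["name"].strip(),
                    mass_shift=float(row["mass_shift"]),
                    residues=scope,
                )
            )
    return PTMRegistry(defs, allow_excess=allow_excess)


def default_registry() -> PTMRegistry:
    """Registry bundled with the package: common artefactual PTMs."""
    with resources.as_file(resources.files("ionforest.data") / "ptms.csv") as p:
        return load_ptm_table(p)
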