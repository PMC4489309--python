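"""Parse, validate and render peptides in the ``H-P-OH`` grammar.

A peptide string has the shape ``<nterm>-<body>-<cterm>``: the N-terminal
token is ``H`` (unmodified) or a registered lowercase symbol, the C-terminal
token is ``OH`` or a registered lowercase symbol, and the body is a run of
capital 1-letter residue codes, each optionally preceded by a lowercase
modification symbol that binds to the next capital. ``H-SAoxMPLE-OH``
carries the modification ``ox`` on the ``M`` at position 3 (1-based).

No upper length limit is enforced; any peptide of length >= 2 over the 20
standard residues is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .constants import RESIDUE_MASSES, WATER
from .ptms import PTMError, PTMRegistry

DEFAULT_N_TERM = "H-"
DEFAULT_C_TERM = "-OH"

_BODY_TOKEN = re.compile(r"([a-z]*)([A-Z])")


class PeptideError(ValueError):
    """Malformed peptide string or invalid peptide structure."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with positioned modifications and termini.

    Parameters
    ----------
    sequence
        Capital 1-letter residue codes, length >= 2.
    residue_mods
        Map from 1-based residue position to the PTM symbol at that
        position; at most one symbol per position.
    n_term, c_term
        Terminal symbols including their dash (``H-`` / ``-OH`` defaults).
    """

    sequence: str
    residue_mods: Mapping[int, str] = field(default_factory=dict)
    n_term: str = DEFAULT_N_TERM
    c_term: str = DEFAULT_C_TERM

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise PeptideError("peptide length must be >= 2")
        for aa in self.sequence:
            if aa not in RESIDUE_MASSES:
                raise PeptideError(f"invalid residue code {aa!r}")
        mods = dict(self.residue_mods)
        for pos, sym in mods.items():
            if not 1 <= pos <= len(self.sequence):
                raise PeptideError(f"mod position {pos} outside [1, {len(self.sequence)}]")
            if not sym or not sym.islower():
                raise PeptideError(f"mod symbol {sym!r} must be lowercase")
        if not self.n_term.endswith("-"):
            raise PeptideError(f"N-terminal symbol {self.n_term!r} must end with '-'")
        if not self.c_term.startswith("-"):
            raise PeptideError(f"C-terminal symbol {self.c_term!r} must start with '-'")
        object.__setattr__(self, "residue_mods", mods)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_modified(self) -> bool:
        return bool(self.residue_mods) or self.n_term != DEFAULT_N_TERM or self.c_term != DEFAULT_C_TERM

    def mod_at(self, pos: int) -> str | None:
        """PTM symbol at 1-based position `pos`, or None."""
        return self.residue_mods.get(pos)

    def validate(self, registry: PTMRegistry) -> None:
        """Check every non-default symbol against `registry` and its scope."""
        for pos, sym in self.residue_mods.items():
            d = registry.get(sym)
            if not d.is_internal:
                raise PeptideError(f"terminal symbol {sym!r} used at residue position {pos}")
            aa = self.sequence[pos - 1]
            if not d.allows(aa):
                raise PeptideError(
                    f"PTM {sym!r} not allowed on residue {aa!r} at position {pos}; "
                    f"scope is {sorted(d.residues)}"
                )
        if self.n_term != DEFAULT_N_TERM:
            if not registry.get(self.n_term).is_n_term:
                raise PeptideError(f"{self.n_term!r} is not an N-terminal symbol")
        if self.c_term != DEFAULT_C_TERM:
            if not registry.get(self.c_term).is_c_term:
                raise PeptideError(f"{self.c_term!r} is not a C-terminal symbol")


def parse_peptide(text: str, registry: PTMRegistry) -> Peptide:
    """Parse an ``H-P-OH`` style string into a :class:`Peptide`.

    Lowercase runs bind to the next capital letter; the leading token
    (before the first dash) is the N-terminal symbol and the trailing
    token (after the last dash) the C-terminal symbol. Every non-default
    symbol must be registered and within its residue scope.
    """
    if not text:
        raise PeptideError("empty peptide string")
    first = text.find("-")
    last = text.rfind("-")
    if first == -1 or first == last:
        raise PeptideError(
            f"peptide {text!r} does not match '<nterm>-<body>-<cterm>'"
        )
    head, body, tail = text[:first], text[first + 1 : last], text[last + 1 :]
    if not head or not tail or not body:
        raise PeptideError(f"peptide {text!r} has an empty grammar token")
    n_term = DEFAULT_N_TERM if head == "H" else head + "-"
    c_term = DEFAULT_C_TERM if tail == "OH" else "-" + tail

    sequence: list[str] = []
    mods: dict[int, str] = {}
    pos = 0
    for run, aa in _BODY_TOKEN.findall(body):
        pos += 1
        sequence.append(aa)
        if run:
            mods[pos] = run
    consumed = sum(len(r) + 1 for r, _ in _BODY_TOKEN.findall(body))
    if consumed != len(body):
        # leftover characters: digits, trailing lowercase with no residue, ...
        raise PeptideError(f"peptide body {body!r} is not lowercase-runs + capitals")
    p = Peptide("".join(sequence), mods, n_term, c_term)
    p.validate(registry)
    return p


def render_peptide(p: Peptide) -> str:
    """Inverse of :func:`parse_peptide`: the canonical peptide string."""
    parts = [p.n_term]
    for i, aa in enumerate(p.sequence, start=1):
        sym = p.residue_mods.get(i)
        if sym:
            parts.append(sym)
        parts.append(aa)
    parts.append(p.c_term)
    return "".join(parts)


def peptide_mass(p: Peptide, registry: PTMRegistry) -> float:
    """Monoisotopic neutral mass (Da): residues + water + all PTM shifts.

    The default ``H-``/``-OH`` termini contribute the water term; modified
    termini add their registered mass shift on top.
    """
    p.validate(registry)
    mass = sum(RESIDUE_MASSES[aa] for aa in p.sequence) + WATER
    for sym in p.residue_mods.values():
        mass += registry.get(sym).mass_shift
    if p.n_term != DEFAULT_N_TERM:
        mass += registry.get(p.n_term).mass_shift
    if p.c_term != DEFAULT_C_TERM:
        mass += registry.get(p.c_term).mass_shift
    return mass


def terminal_shift(p: Peptide, registry: PTMRegistry, *, n: bool) -> float:
    """Mass shift of the N- (or C-) terminal modification, 0 if default."""
    sym = p.n_term if n else p.c_term
    default = DEFAULT_N_TERM if n else DEFAULT_C_TERM
    return 0.0 if sym == default else registry.get(sym).mass_shift
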