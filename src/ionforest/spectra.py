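"""Observed-spectrum I/O and conversion to regression targets.

MGF reading/writing is delegated to :mod:`pyteomics.mgf`; this module adds
the precursor-charge policy (only 2+ and 3+ spectra are kept), the
peptide-aware TITLE contract for predicted spectra, and the annotation step
that turns an observed spectrum into normalized log-intensity targets for
each theoretical fragment ion.

Annotation transform: matched raw intensities are divided by the total ion
current (TIC) of the spectrum, then mapped through ``x -> log2(x + eps)``
with ``eps`` = 0.001 x the median nonzero normalized intensity of that
spectrum. Unmatched ions receive the baseline ``log2(eps)``, so "absent"
is learned as lowest intensity rather than dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .constants import PROTON
from .ions import ION_SERIES, FragmentIon, iter_fragments
from .peptides import Peptide, peptide_mass, render_peptide
from .ptms import PTMRegistry

#: Precursor charge states the models cover.
SUPPORTED_CHARGES = (2, 3)

#: Default absolute peak-matching tolerance (Da), suited to de-isotoped
#: high-resolution spectra.
DEFAULT_TOLERANCE = 0.02

#: Identifier of the annotation transform, stored in model metadata.
NORMALIZATION_ID = "tic-log2-v1"

_EPS_FRACTION = 1e-3
_EPS_FLOOR = 1e-9


class MGFError(ValueError):
    """Malformed MGF content."""


@dataclass
class ObservedSpectrum:
    """One MS2 spectrum: title, precursor info and the peak list."""

    title: str
    precursor_charge: int
    pepmass: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise MGFError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise MGFError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        """Total ion current: sum of all peak intensities."""
        return float(self.intensity.sum())


@dataclass
class TargetVector:
    """Normalized log2 target intensities for the four ion series.

    ``targets[(series, ion_charge)]`` is a length L-1 vector aligned with
    fragment indices 1..L-1; ``matched`` flags which entries were matched
    to an observed peak; ``epsilon`` is the spectrum's transform offset.
    """

    targets: dict[tuple[str, int], np.ndarray]
    matched: dict[tuple[str, int], np.ndarray]
    epsilon: float
    n_sites: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.targets.values()}
        if set(self.targets) != set(ION_SERIES) or len(lengths) != 1:
            raise ValueError("targets must cover all four series with equal lengths")
        self.n_sites = lengths.pop()

    @property
    def baseline(self) -> float:
        return float(np.log2(self.epsilon))

    def pooled(self) -> np.ndarray:
        """All four series concatenated in canonical series order."""
        return np.concatenate([self.targets[k] for k in ION_SERIES])

    def pooled_matched(self) -> np.ndarray:
        return np.concatenate([self.matched[k] for k in ION_SERIES])

    def n_matched(self) -> int:
        return int(self.pooled_matched().sum())


def _begin_ions_lines(path: str | Path) -> list[int]:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip().upper() == "BEGIN IONS":
                lines.append(i)
    return lines


def read_mgf(path: str | Path) -> list[ObservedSpectrum]:
    """Read an MGF file into :class:`ObservedSpectrum` records.

    Spectra whose CHARGE is not 2+ or 3+ are skipped (a single warning
    reports the count). A malformed block raises :class:`MGFError` naming
    the line where the offending block starts.
    """
    spectra: list[ObservedSpectrum] = []
    skipped = 0
    block = 0
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for entry in reader:
                block += 1
                params = entry["params"]
                charges = params.get("charge")
                charge = int(charges[0]) if charges else 0
                if charge not in SUPPORTED_CHARGES:
                    skipped += 1
                    continue
                pepmass = params.get("pepmass", (0.0,))[0] or 0.0
                spectra.append(
                    ObservedSpectrum(
                        title=str(params.get("title", "")),
                        precursor_charge=charge,
                        pepmass=float(pepmass),
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    except Exception as exc:
        starts = _begin_ions_lines(path)
        line = starts[block] if block < len(starts) else (starts[-1] if starts else 0)
        raise MGFError(
            f"malformed MGF block starting at line {line} of {path}: {exc}"
        ) from exc
    if skipped:
        warnings.warn(
            f"skipped {skipped} spectra with unsupported precursor charge "
            f"(supported: {SUPPORTED_CHARGES})",
            stacklevel=2,
        )
    return spectra


PredictedEntry = tuple[Peptide, int, Sequence[FragmentIon]]


def write_mgf(
    entries: Iterable[PredictedEntry],
    registry: PTMRegistry,
    path: str | Path,
    *,
    keep_zeros: bool = True,
) -> int:
    """Write predicted spectra to MGF; returns the number of blocks written.

    TITLE is the rendered peptide string, CHARGE is ``<c>+`` and PEPMASS
    the precursor m/z. With ``keep_zeros=False`` zero-intensity ions are
    pruned from the peak list.
    """
    blocks = []
    n = 0
    for peptide, charge, ions in entries:
        rows = sorted(ions, key=lambda ion: ion.mz)
        if any(ion.intensity is None for ion in rows):
            raise ValueError("write_mgf requires intensities on all ions")
        if not keep_zeros:
            rows = [ion for ion in rows if ion.intensity > 0]
        precursor_mz = (peptide_mass(peptide, registry) + charge * PROTON) / charge
        blocks.append(
            {
                "m/z array": np.array([ion.mz for ion in rows]),
                "intensity array": np.array([ion.intensity for ion in rows]),
                "params": {
                    "title": render_peptide(peptide),
                    "pepmass": precursor_mz,
                    "charge": f"{charge}+",
                },
            }
        )
        n += 1
    _mgf.write(blocks, str(path), file_mode="w")
    return n


def observed_to_mgf(spectra: Iterable[ObservedSpectrum], path: str | Path) -> int:
    """Write :class:`ObservedSpectrum` records back to MGF (round-trip aid)."""
    blocks = []
    for s in spectra:
        blocks.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.title,
                    "pepmass": s.pepmass,
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(blocks, str(path), file_mode="w")
    return len(blocks)


def annotate(
    p: Peptide,
    s: ObservedSpectrum,
    registry: PTMRegistry,
    tol: float = DEFAULT_TOLERANCE,
) -> TargetVector:
    """Match theoretical ions to observed peaks and build the target vector.

    Each theoretical ion takes the intensity of the most intense observed
    peak within ``+-tol`` of its m/z (one observed peak may serve several
    near-isobaric ions). Matched intensities are TIC-normalized and log2
    transformed; unmatched entries get the baseline ``log2(eps)``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    tic = s.tic
    norm = s.intensity / tic if tic > 0 else s.intensity
    nonzero = norm[norm > 0]
    eps = _EPS_FRACTION * float(np.median(nonzero)) if nonzero.size else _EPS_FLOOR
    baseline = np.log2(eps)

    n_sites = len(p) - 1
    targets: dict[tuple[str, int], np.ndarray] = {}
    matched: dict[tuple[str, int], np.ndarray] = {}
    for key in ION_SERIES:
        targets[key] = np.full(n_sites, baseline)
        matched[key] = np.zeros(n_sites, dtype=bool)
    for ion in iter_fragments(p, registry):
        lo = np.searchsorted(s.mz, ion.mz - tol, side="left")
        hi = np.searchsorted(s.mz, ion.mz + tol, side="right")
        if hi > lo:
            key = (ion.series, ion.ion_charge)
            x = float(norm[lo:hi].max())
            targets[key][ion.index - 1] = np.log2(x + eps)
            matched[key][ion.index - 1] = True
    return TargetVector(targets, matched, eps)


CSV_HEADER = ("peptide", "precursor_charge", "series", "ion_charge", "index", "mz", "intensity")


def write_csv(predictions: Iterable[PredictedEntry], path: str | Path) -> int:
    """Write predicted intensities as CSV, one row per ion; returns row count."""
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for peptide, charge, ions in predictions:
            text = render_peptide(peptide)
            for ion in sorted(ions, key=lambda ion: ion.mz):
                writer.writerow(
                    (text, charge, ion.series, ion.ion_charge, ion.index,
                     repr(ion.mz), repr(float(ion.intensity)))
                )
                n += 1
    return n
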