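"""Fixed-length feature vectors for (peptide, precursor charge, site).

A cleavage site ``i`` (1-based, 1..L-1) splits the peptide into the prefix
1..i (the b fragment) and the suffix i+1..L (the y fragment). The encoding
describes the site through global context (length, relative position,
precursor charge, property-scale means), a local identity window of two
residues on each side of the cleavage bond, prefix/suffix residue
composition, and modification features that encode "modified + how heavy"
but never the PTM identity — two different registered PTMs of equal mass
at the same position produce identical vectors except for nothing at all,
and PTMs of different mass differ only in the mass-shift features.

The schema is versioned; trained models store the version and refuse to
predict against a different one.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

import numpy as np

from .constants import STANDARD_RESIDUES
from .peptides import Peptide, terminal_shift
from .ptms import PTMRegistry

SCHEMA_VERSION = "v1-146"

#: Padding symbol for window positions outside the peptide.
PAD = "."

_WINDOW_OFFSETS = (-1, 0, 1, 2)  # residue positions site-1 .. site+2
_ALPHABET = STANDARD_RESIDUES + (PAD,)
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SCALES = ("basicity", "hydrophobicity", "helicity", "isoelectric")

N_FEATURES = (
    1  # peptide length
    + 1  # relative site position
    + 2  # precursor-charge indicators (2+, 3+)
    + len(_SCALES) * 3  # property means: full / prefix / suffix
    + len(_WINDOW_OFFSETS) * len(_ALPHABET)  # identity window one-hots
    + 2 * len(STANDARD_RESIDUES)  # residue counts in prefix / suffix
    + 2  # total PTM mass shift in prefix / suffix
    + 2  # count of modified residues in prefix / suffix
    + 2  # modified-at-site / modified-at-site+1 indicators
)


@lru_cache(maxsize=1)
def property_table() -> dict[str, np.ndarray]:
    """Bundled per-residue property scales, one vector per scale.

    Vectors are indexed by position in :data:`STANDARD_RESIDUES`.
    """
    rows: dict[str, dict[str, float]] = {}
    with resources.as_file(resources.files("ionforest.data") / "aa_properties.csv") as p:
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rows[row["residue"]] = {s: float(row[s]) for s in _SCALES}
    missing = set(STANDARD_RESIDUES) - set(rows)
    if missing:
        raise ValueError(f"property table incomplete; missing {sorted(missing)}")
    return {
        s: np.array([rows[aa][s] for aa in STANDARD_RESIDUES]) for s in _SCALES
    }


def feature_names() -> list[str]:
    """Human-readable names for the schema's features, in order."""
    names = ["length", "rel_position", "charge_is_2", "charge_is_3"]
    for s in _SCALES:
        names += [f"{s}_mean_full", f"{s}_mean_prefix", f"{s}_mean_suffix"]
    for off in _WINDOW_OFFSETS:
        for aa in _ALPHABET:
            names.append(f"window{off:+d}_is_{aa}")
    names += [f"count_prefix_{aa}" for aa in STANDARD_RESIDUES]
    names += [f"count_suffix_{aa}" for aa in STANDARD_RESIDUES]
    names += [
        "ptm_mass_prefix",
        "ptm_mass_suffix",
        "n_modified_prefix",
        "n_modified_suffix",
        "modified_at_site",
        "modified_at_site_plus_1",
    ]
    assert len(names) == N_FEATURES
    return names


def encode_peptide(
    p: Peptide, registry: PTMRegistry, precursor_charge: int
) -> np.ndarray:
    """Encode all L-1 cleavage sites at once; returns (L-1, N_FEATURES).

    Row ``i`` (0-based) is the vector for site ``i+1``. Vectorized over
    sites via cumulative sums so that large training sets encode quickly.
    """
    L = len(p)
    n_sites = L - 1
    aa_idx = np.array([_AA_INDEX[aa] for aa in p.sequence])
    out = np.zeros((n_sites, N_FEATURES), dtype=np.float64)
    sites = np.arange(1, L)  # 1-based cleavage sites

    col = 0
    out[:, col] = L
    col += 1
    out[:, col] = sites / n_sites
    col += 1
    out[:, col] = 1.0 if precursor_charge == 2 else 0.0
    out[:, col + 1] = 1.0 if precursor_charge == 3 else 0.0
    col += 2

    props = property_table()
    for s in _SCALES:
        vals = props[s][aa_idx]
        csum = np.cumsum(vals)
        total = csum[-1]
        out[:, col] = total / L
        out[:, col + 1] = csum[:-1] / sites
        out[:, col + 2] = (total - csum[:-1]) / (L - sites)
        col += 3

    # identity window one-hots: residue positions site-1 .. site+2
    for off in _WINDOW_OFFSETS:
        pos = sites + off  # 1-based residue position
        valid = (pos >= 1) & (pos <= L)
        sym = np.full(n_sites, _AA_INDEX[PAD])
        sym[valid] = aa_idx[pos[valid] - 1]
        out[np.arange(n_sites), col + sym] = 1.0
        col += len(_ALPHABET)

    onehot = np.zeros((L, len(STANDARD_RESIDUES)))
    onehot[np.arange(L), aa_idx] = 1.0
    ccount = np.cumsum(onehot, axis=0)
    out[:, col : col + 20] = ccount[:-1]
    out[:, col + 20 : col + 40] = ccount[-1] - ccount[:-1]
    col += 40

    mod_mass = np.zeros(L)
    mod_flag = np.zeros(L)
    for pos, sym in p.residue_mods.items():
        mod_mass[pos - 1] = registry.get(sym).mass_shift
        mod_flag[pos - 1] = 1.0
    mcum = np.cumsum(mod_mass)
    fcum = np.cumsum(mod_flag)
    nshift = terminal_shift(p, registry, n=True)
    cshift = terminal_shift(p, registry, n=False)
    out[:, col] = mcum[:-1] + nshift
    out[:, col + 1] = (mcum[-1] - mcum[:-1]) + cshift
    out[:, col + 2] = fcum[:-1]
    out[:, col + 3] = fcum[-1] - fcum[:-1]
    out[:, col + 4] = mod_flag[sites - 1]
    out[:, col + 5] = mod_flag[sites]  # residue at site+1; sites <= L-1
    col += 6
    assert col == N_FEATURES
    return out


def encode_site(
    p: Peptide, registry: PTMRegistry, precursor_charge: int, site: int
) -> np.ndarray:
    """Feature vector for one cleavage site (1 <= site <= L-1)."""
    if not 1 <= site <= len(p) - 1:
        raise ValueError(f"site {site} outside [1, {len(p) - 1}]")
    return encode_peptide(p, registry, precursor_charge)[site - 1]
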