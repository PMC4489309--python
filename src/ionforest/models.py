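"""Per-method, per-charge fragment-intensity regressors.

One :class:`IntensityModel` is trained for a single fragmentation method
(CID or HCD) and a single precursor charge (2+ or 3+), and bundles four
random-forest regressors — one per ion series (b+, y+, b++, y++). The
feature schema version and full training configuration travel with the
model so that a loaded model refuses to run against a mismatched encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import encoding
from .encoding import SCHEMA_VERSION, encode_peptide
from .ions import ION_SERIES, FragmentIon, iter_fragments
from .peptides import Peptide
from .ptms import PTMRegistry
from .spectra import (
    DEFAULT_TOLERANCE,
    NORMALIZATION_ID,
    ObservedSpectrum,
    TargetVector,
    annotate,
)

METHODS = ("CID", "HCD")


class SchemaMismatchError(RuntimeError):
    """Model and encoder feature schemas disagree."""


@dataclass(frozen=True)
class TrainingConfig:
    """Forest and preprocessing hyperparameters recorded in model metadata.

    Defaults (50 trees, sqrt feature subsampling, unlimited depth) keep
    single-CPU training at desk scale in the low minutes for ~100k
    examples per series while leaving accuracy on easy targets near the
    ceiling.
    """

    n_trees: int = 50
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    seed: int = 1
    tolerance: float = DEFAULT_TOLERANCE
    normalization: str = NORMALIZATION_ID


@dataclass
class TrainingSet:
    """Stacked (features, per-series targets) examples for one method+charge."""

    method: str
    precursor_charge: int
    X: np.ndarray  # (n_examples, n_features); shared across series
    y: dict[tuple[str, int], np.ndarray]  # per series, (n_examples,)
    epsilons: np.ndarray  # per source spectrum, annotation eps
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if set(self.y) != set(ION_SERIES):
            raise ValueError("training set must cover all four ion series")
        for k, v in self.y.items():
            if v.shape != (n,):
                raise ValueError(f"target length mismatch for series {k}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite targets in series {k}")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]


def build_training_set(
    psms: Sequence[tuple[Peptide, ObservedSpectrum]],
    method: str,
    registry: PTMRegistry,
    tol: float = DEFAULT_TOLERANCE,
) -> dict[int, TrainingSet]:
    """Annotate and encode PSMs, partitioned by precursor charge.

    Every PSM contributes one example per cleavage site per ion series;
    returns one :class:`TrainingSet` per precursor charge present.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if not psms:
        raise ValueError("empty PSM list")
    buckets: dict[int, dict] = {}
    for peptide, spectrum in psms:
        charge = spectrum.precursor_charge
        b = buckets.setdefault(
            charge, {"X": [], "y": {k: [] for k in ION_SERIES}, "eps": []}
        )
        tv = annotate(peptide, spectrum, registry, tol)
        b["X"].append(encode_peptide(peptide, registry, charge))
        for k in ION_SERIES:
            b["y"][k].append(tv.targets[k])
        b["eps"].append(tv.epsilon)
    out = {}
    for charge, b in buckets.items():
        out[charge] = TrainingSet(
            method=method,
            precursor_charge=charge,
            X=np.vstack(b["X"]),
            y={k: np.concatenate(v) for k, v in b["y"].items()},
            epsilons=np.array(b["eps"]),
        )
    return out


@dataclass
class IntensityModel:
    """Four fitted per-series regressors plus provenance metadata."""

    method: str
    precursor_charge: int
    regressors: dict[tuple[str, int], RandomForestRegressor]
    config: TrainingConfig
    schema_version: str = SCHEMA_VERSION
    reference_epsilon: float = 1e-6
    n_training_examples: int = 0

    def check_schema(self) -> None:
        if self.schema_version != encoding.SCHEMA_VERSION:
            raise SchemaMismatchError(
                f"model was trained with feature schema {self.schema_version!r} "
                f"but the running encoder is {encoding.SCHEMA_VERSION!r}"
            )

    @property
    def metadata(self) -> dict:
        return {
            "method": self.method,
            "precursor_charge": self.precursor_charge,
            "schema_version": self.schema_version,
            "reference_epsilon": self.reference_epsilon,
            "n_training_examples": self.n_training_examples,
            "training_config": asdict(self.config),
        }


def train(ts: TrainingSet, config: TrainingConfig = TrainingConfig()) -> IntensityModel:
    """Fit one random forest per ion series; reproducible given config.seed."""
    if ts.n_examples == 0:
        raise ValueError("empty training set")
    if ts.schema_version != SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"training set schema {ts.schema_version!r} != encoder {SCHEMA_VERSION!r}"
        )
    regressors = {}
    for i, key in enumerate(ION_SERIES):
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.max_features,
            random_state=config.seed + i,
            n_jobs=1,
        )
        rf.fit(ts.X, ts.y[key])
        regressors[key] = rf
    eps = float(np.median(ts.epsilons)) if ts.epsilons.size else 1e-6
    return IntensityModel(
        method=ts.method,
        precursor_charge=ts.precursor_charge,
        regressors=regressors,
        config=config,
        reference_epsilon=eps,
        n_training_examples=ts.n_examples,
    )


def predict_targets(
    m: IntensityModel, p: Peptide, registry: PTMRegistry, precursor_charge: int
) -> dict[tuple[str, int], np.ndarray]:
    """Raw model outputs on the normalized-log2 target scale, per series."""
    m.check_schema()
    if precursor_charge != m.precursor_charge:
        raise ValueError(
            f"model covers precursor charge {m.precursor_charge}+, "
            f"got {precursor_charge}+"
        )
    X = encode_peptide(p, registry, precursor_charge)
    return {k: m.regressors[k].predict(X) for k in ION_SERIES}


def predict_spectrum(
    m: IntensityModel, p: Peptide, registry: PTMRegistry, precursor_charge: int
) -> list[FragmentIon]:
    """Predict all 4 x (L-1) fragment intensities for a peptide.

    Model outputs are inverse-transformed from the log2 normalized scale
    back to relative intensities and floored at zero (MGF cannot carry
    negative peaks). Any peptide length >= 2 is accepted.
    """
    log_targets = predict_targets(m, p, registry, precursor_charge)
    ions = []
    for ion in iter_fragments(p, registry):
        t = log_targets[(ion.series, ion.ion_charge)][ion.index - 1]
        intensity = max(0.0, float(2.0**t - m.reference_epsilon))
        ions.append(
            FragmentIon(ion.series, ion.ion_charge, ion.index, ion.mz, intensity)
        )
    return ions


def save_model(m: IntensityModel, path: str | Path) -> None:
    """Serialize the model bundle (regressors + JSON-able metadata)."""
    payload = {"metadata": m.metadata, "regressors": m.regressors}
    joblib.dump(payload, path, compress=3)


def load_model(path: str | Path) -> IntensityModel:
    """Load a model bundle; refuses a schema mismatched with the encoder."""
    try:
        payload = joblib.load(path)
        meta = payload["metadata"]
        regressors = payload["regressors"]
    except SchemaMismatchError:
        raise
    except Exception as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    model = IntensityModel(
        method=meta["method"],
        precursor_charge=meta["precursor_charge"],
        regressors=regressors,
        config=TrainingConfig(**meta["training_config"]),
        schema_version=meta["schema_version"],
        reference_epsilon=meta["reference_epsilon"],
        n_training_examples=meta["n_training_examples"],
    )
    model.check_schema()
    return model
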