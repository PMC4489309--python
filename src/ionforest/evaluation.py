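"""Per-PSM Pearson-R scoring and boxplot-style distribution summaries.

Each peptide-to-spectrum match is scored by a single Pearson correlation
coefficient between the predicted and observed fragment intensities, with
the four ion series concatenated into one vector per PSM (per-series R is
available behind a flag). Zero-variance vectors make Pearson undefined;
such PSMs are flagged degenerate and excluded from summaries, with their
count reported rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ions import ION_SERIES
from .models import IntensityModel, predict_targets
from .peptides import Peptide
from .ptms import PTMRegistry
from .spectra import DEFAULT_TOLERANCE, ObservedSpectrum, annotate

PTM_CLASSES = ("no_ptm", "mox", "cmm", "other")


@dataclass(frozen=True)
class EvaluationRecord:
    """Pearson R for one PSM plus its grouping labels."""

    psm_id: str
    R: float
    degenerate: bool
    spectrum_method: str
    model_method: str
    precursor_charge: int
    ptm_class: str
    n_matched: int


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number boxplot summary plus mean for one group of R values."""

    n: int
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def pearson_r(pred: Sequence[float], obs: Sequence[float]) -> tuple[float, bool]:
    """Pearson correlation and a degeneracy flag.

    Returns ``(nan, True)`` when either vector has zero variance, where
    the coefficient is undefined. Vectors must have equal length >= 3.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 points for a meaningful correlation")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return math.nan, True
    r = stats.pearsonr(pred, obs).statistic
    return float(r), False


def classify_ptms(p: Peptide, registry: PTMRegistry) -> str:
    """Bucket a peptide by its modifications.

    ``no_ptm`` — unmodified; ``mox`` — only methionine oxidation; ``cmm``
    — only cysteine carbamidomethylation; ``other`` — anything else
    (including mixtures and terminal modifications).
    """
    if not p.is_modified:
        return "no_ptm"
    if p.n_term != "H-" or p.c_term != "-OH":
        return "other"
    kinds = set()
    for pos, sym in p.residue_mods.items():
        name = registry.get(sym).name.lower()
        aa = p.sequence[pos - 1]
        if name.startswith("oxidation") and aa == "M":
            kinds.add("mox")
        elif name.startswith("carbamidomethyl") and aa == "C":
            kinds.add("cmm")
        else:
            kinds.add("other")
    return kinds.pop() if len(kinds) == 1 else "other"


def evaluate(
    model: IntensityModel,
    psms: Sequence[tuple[Peptide, ObservedSpectrum]],
    registry: PTMRegistry,
    tol: float = DEFAULT_TOLERANCE,
    *,
    spectrum_method: str,
    per_series: bool = False,
) -> list[EvaluationRecord]:
    """Score every PSM against the model's predictions.

    Correlations are computed on the normalized log2 intensity scale —
    the same scale the targets are trained on — pooling all four ion
    series per PSM. With ``per_series=True`` each series yields its own
    record (psm_id suffixed with the series label). Cross-method
    evaluation is simply passing PSMs whose ``spectrum_method`` differs
    from ``model.method``.
    """
    records = []
    for i, (peptide, spectrum) in enumerate(psms):
        if spectrum.precursor_charge != model.precursor_charge:
            raise ValueError(
                f"PSM {i} has precursor charge {spectrum.precursor_charge}+ "
                f"but the model covers {model.precursor_charge}+"
            )
        tv = annotate(peptide, spectrum, registry, tol)
        pred = predict_targets(model, peptide, registry, spectrum.precursor_charge)
        ptm_class = classify_ptms(peptide, registry)
        base = dict(
            spectrum_method=spectrum_method,
            model_method=model.method,
            precursor_charge=spectrum.precursor_charge,
            ptm_class=ptm_class,
        )
        if per_series:
            for key in ION_SERIES:
                series, z = key
                r, degen = pearson_r(pred[key], tv.targets[key])
                records.append(
                    EvaluationRecord(
                        psm_id=f"psm{i}:{series}{'+' * z}",
                        R=r,
                        degenerate=degen,
                        n_matched=int(tv.matched[key].sum()),
                        **base,
                    )
                )
        else:
            pooled_pred = np.concatenate([pred[k] for k in ION_SERIES])
            r, degen = pearson_r(pooled_pred, tv.pooled())
            records.append(
                EvaluationRecord(
                    psm_id=f"psm{i}",
                    R=r,
                    degenerate=degen,
                    n_matched=tv.n_matched(),
                    **base,
                )
            )
    return records


def records_frame(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame, one row per record."""
    return pd.DataFrame([asdict(r) for r in records])


def summarize(
    records: Sequence[EvaluationRecord] | pd.DataFrame,
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Boxplot-style summaries of R per group.

    Quartiles use linear interpolation; whiskers follow the Tukey
    convention (most extreme datum within 1.5 x IQR of the box).
    Degenerate records are excluded; their count is in ``n_degenerate``.
    Empty groups are omitted.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    group_by = list(group_by)

    def _one(sub: pd.DataFrame) -> pd.Series:
        vals = sub.loc[~sub["degenerate"], "R"].to_numpy()
        n_degen = int(sub["degenerate"].sum())
        if vals.size == 0:
            return pd.Series(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_low = vals[vals >= q1 - 1.5 * iqr]
        in_high = vals[vals <= q3 + 1.5 * iqr]
        return pd.Series(
            {
                "n": vals.size,
                "n_degenerate": n_degen,
                "mean": vals.mean(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": in_low.min(),
                "whisker_high": in_high.max(),
            }
        )

    if not group_by:
        return _one(df).to_frame().T
    out = (
        df.groupby(group_by, sort=True)
        .apply(_one, include_groups=False)
        .dropna(how="all")
        .reset_index()
    )
    return out


def boxplot(
    records: Sequence[EvaluationRecord] | pd.DataFrame,
    group_by: Sequence[str],
    path: str,
) -> None:
    """Save a grouped boxplot of R values (Tukey whiskers) to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df[~df["degenerate"]]
    groups = df.groupby(list(group_by), sort=True)
    labels = [
        "/".join(str(v) for v in (key if isinstance(key, tuple) else (key,)))
        for key, _ in groups
    ]
    data = [sub["R"].to_numpy() for _, sub in groups]
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(data)), 4))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_ylabel("Pearson R (predicted vs observed intensities)")
    ax.set_ylim(-1.05, 1.05)
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
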