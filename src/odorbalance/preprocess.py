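"""Cleaning steps applied before any modeling.

Two steps, in a fixed order:

1. drop compounds that are zero or missing in more than half of the samples
   (below-LOD and absent are indistinguishable downstream, so both count);
2. drop outlier samples, flagged independently within each quality group by
   the local outlier factor (LOF) on per-group z-scored concentrations.

Both steps return a removal report that fully accounts for the change in
table dimensions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .exceptions import EmptyResultError, InsufficientDataError

__all__ = ["filter_sparse_compounds", "remove_outlier_samples"]


def filter_sparse_compounds(
    table: pd.DataFrame, max_zero_fraction: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop compounds with zero/missing values in more than half the samples.

    A compound is removed when its zero-or-missing count *strictly* exceeds
    ``max_zero_fraction * n_samples``; a compound zeroed in exactly half the
    samples is retained.

    Returns
    -------
    (filtered table, report)
        The report has one row per dropped compound with its zero count and
        zero fraction.
    """
    n = len(table.index)
    zero_counts = ((table.isna()) | (table == 0)).sum(axis=0)
    dropped = zero_counts[zero_counts > max_zero_fraction * n]
    kept = table.drop(columns=dropped.index)
    if kept.shape[1] == 0:
        raise EmptyResultError(
            f"sparse-compound filter removed all {table.shape[1]} compounds"
        )
    report = pd.DataFrame(
        {
            "compound": dropped.index,
            "zero_count": dropped.to_numpy(),
            "zero_fraction": dropped.to_numpy() / n,
        }
    ).reset_index(drop=True)
    return kept, report


def _zscore_columns(block: pd.DataFrame) -> np.ndarray:
    x = block.to_numpy(dtype=float)
    x = np.nan_to_num(x, nan=0.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant compounds carry no density information
    return (x - mu) / sd


def remove_outlier_samples(
    table: pd.DataFrame,
    groups: pd.Series,
    n_neighbors: int = 20,
    lof_threshold: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove density outliers within each group via the local outlier factor.

    Concentrations are z-scored per compound *within* each group before LOF so
    high-abundance compounds (ethyl acetate scale) do not dominate distances.
    A sample is flagged when its LOF score exceeds *lof_threshold* (the usual
    "clearly more isolated than its neighbours" cut at 1.5).  ``n_neighbors``
    is clamped to group size − 1 with a warning for small groups.  The
    procedure is deterministic.

    Returns
    -------
    (filtered table, report)
        Report rows: sample, group, LOF score, removed flag for every sample.
    """
    records = []
    keep: list[str] = []
    for label in pd.unique(groups):
        members = [s for s in table.index if groups.get(s) == label]
        block = table.loc[members]
        k = n_neighbors
        if k >= len(members):
            k = max(1, len(members) - 1)
            warnings.warn(
                f"group '{label}' has {len(members)} samples; "
                f"clamping LOF n_neighbors from {n_neighbors} to {k}"
            )
        lof = LocalOutlierFactor(n_neighbors=k)
        lof.fit(_zscore_columns(block))
        scores = -lof.negative_outlier_factor_
        flagged = scores > lof_threshold
        for sample, score, out in zip(members, scores, flagged):
            records.append(
                {"sample": sample, "group": label, "lof_score": float(score), "removed": bool(out)}
            )
            if not out:
                keep.append(sample)
        if (~flagged).sum() < 3:
            raise InsufficientDataError(
                f"outlier removal would leave group '{label}' with "
                f"{int((~flagged).sum())} samples (<3)"
            )
    unlabeled = [s for s in table.index if s not in groups.index]
    if unlabeled:
        raise InsufficientDataError(f"samples without group labels: {', '.join(unlabeled)}")
    kept = table.loc[[s for s in table.index if s in set(keep)]]
    report = pd.DataFrame.from_records(records)
    return kept, report
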