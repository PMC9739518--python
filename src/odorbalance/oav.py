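"""Odor activity values (OAV) and per-descriptor accumulated OAVs.

The OAV of a compound in a sample is its concentration divided by its odor
threshold in the matrix at hand; OAV ≥ 1 marks a potential contributor to the
perceived aroma.  Because a compound can carry several odor descriptors
(furfural: nutty, sweet, bread), per-descriptor profiles use an *accumulated*
OAV: for each descriptor, the sum of the OAVs of every compound carrying it,
with multi-descriptor compounds contributing their full OAV to each of their
descriptors.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["compute_oav", "compute_oav_sum", "count_oav_above", "descriptor_universe"]


def compute_oav(table: pd.DataFrame, thresholds: pd.Series) -> pd.DataFrame:
    """Elementwise concentration / threshold, samples × compounds.

    Both sides must be in μg/L.  Compounds without a threshold are dropped
    with a warning; missing concentrations stay missing, zeros map to OAV 0.
    """
    missing = [c for c in table.columns if c not in thresholds.index]
    if missing:
        warnings.warn(
            f"{len(missing)} compound(s) lack odor thresholds and were dropped: "
            + ", ".join(missing)
        )
    kept = [c for c in table.columns if c in thresholds.index]
    if not kept:
        raise ValidationError("no compound in the quantity table has an odor threshold")
    t = thresholds.loc[kept].astype(float)
    if (t <= 0).any():
        raise ValidationError("odor thresholds must be strictly positive")
    return table[kept].astype(float).div(t, axis=1)


def descriptor_universe(odors: Mapping[str, Sequence[str]]) -> list[str]:
    """Sorted union of descriptor labels over the mapped compounds."""
    labels = {d for ds in odors.values() for d in ds}
    return sorted(labels)


def compute_oav_sum(oav: pd.DataFrame, odors: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Accumulated OAV per odor descriptor, samples × descriptors.

    Each cell is the sum of the OAVs of all compounds carrying that
    descriptor; compounds absent from the odor map are dropped with a warning.
    Missing OAVs are treated as 0 in the sums.
    """
    if not odors:
        raise ValidationError("odor map is empty")
    unmapped = [c for c in oav.columns if c not in odors]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} compound(s) without odor descriptors dropped from "
            f"accumulated OAVs: " + ", ".join(unmapped)
        )
    mapped = [c for c in oav.columns if c in odors]
    descriptors = descriptor_universe({c: odors[c] for c in mapped})
    filled = oav[mapped].fillna(0.0)
    out = pd.DataFrame(0.0, index=oav.index, columns=descriptors)
    for compound in mapped:
        for d in odors[compound]:
            out[d] += filled[compound]
    return out


def count_oav_above(
    oav: pd.DataFrame,
    groups: pd.Series,
    group_label: str,
    cutoff: float = 1.0,
    inclusive: bool = True,
) -> int:
    """Number of compounds whose group-mean OAV reaches *cutoff*.

    The group mean is the arithmetic mean including zeros (missing cells count
    as 0).  By the usual aroma-screening convention a compound at the cutoff
    counts as a contributor, so the comparison is inclusive (``>=``) by
    default; pass ``inclusive=False`` for a strict ``>``.
    """
    members = [s for s in oav.index if groups.get(s) == group_label]
    if not members:
        raise ValidationError(f"no samples in group '{group_label}'")
    means = oav.loc[members].fillna(0.0).mean(axis=0)
    if inclusive:
        return int((means >= cutoff).sum())
    return int((means > cutoff).sum())
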