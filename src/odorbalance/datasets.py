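"""Packaged reference data.

The package ships a 41-compound reference table for sauce-aroma Baijiu (SAB,
a Chinese sorghum spirit at 53% v/v ethanol): per-compound odor thresholds in
that matrix, odor descriptors, and per-quality-group summary statistics
(mean ± sd of the odor activity value in the relatively-good RG and
relatively-poor RP sensory groups).  It seeds the synthetic cohort generator
and anchors the fixture-based tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import normalize_descriptor

__all__ = [
    "load_reference_table",
    "reference_thresholds",
    "reference_odor_map",
    "reference_oav_summary",
]

_REFERENCE_CSV = "sab_aroma_reference.csv"


def load_reference_table() -> pd.DataFrame:
    """Return the packaged SAB reference table, indexed by compound.

    Columns: ``threshold_ug_per_L``, ``descriptors`` (comma-separated raw
    labels), ``oav_mean_RG``, ``oav_std_RG``, ``oav_mean_RP``, ``oav_std_RP``.
    """
    with resources.files("odorbalance.data").joinpath(_REFERENCE_CSV).open() as fh:
        df = pd.read_csv(fh, index_col="compound")
    return df


def reference_thresholds() -> pd.Series:
    """Odor thresholds (μg/L in 53% v/v ethanol) for the reference compounds."""
    return load_reference_table()["threshold_ug_per_L"].rename("threshold_ug_per_L")


def reference_odor_map() -> dict[str, tuple[str, ...]]:
    """Compound → normalised descriptor tuple for the reference compounds."""
    table = load_reference_table()
    return {
        compound: tuple(normalize_descriptor(tok) for tok in str(cell).split(",") if tok.strip())
        for compound, cell in table["descriptors"].items()
    }


def reference_oav_summary() -> pd.DataFrame:
    """Per-group OAV mean/sd for the reference compounds.

    Columns ``mean_RG``, ``std_RG``, ``mean_RP``, ``std_RP``; these are the
    moments the default synthetic cohort reproduces.
    """
    table = load_reference_table()
    out = table[["oav_mean_RG", "oav_std_RG", "oav_mean_RP", "oav_std_RP"]].copy()
    out.columns = ["mean_RG", "std_RG", "mean_RP", "std_RP"]
    return out
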