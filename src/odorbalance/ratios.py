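"""Log2 OAV-ratio feature engineering.

The classifier's premise is that the *balance* between aromas — not any
single abundance — separates quality grades.  Features are therefore built
as exhaustive ordered pairwise ratios, logged base 2:

* compound level: log2(OAV_a / OAV_b) for every ordered pair (a, b) of
  compounds whose odor-descriptor *sets* differ — pairing, say, a fruity
  ester against a malty aldehyde, but never two compounds describing the
  same odor set;
* descriptor level: log2(OAVsum_d / OAVsum_e) for every ordered descriptor
  pair.

Both directions of a pair are kept as separate features (a/b and b/a carry
the same information but let the forest split on either orientation).  A
ratio with a non-positive numerator or denominator is missing at that
sample; features missing in more than half the samples are dropped and the
remaining gaps are median-imputed, mirroring the sparsity rule used when
cleaning compounds.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "enumerate_pairs",
    "compute_log_ratios",
    "compute_descriptor_ratios",
    "assemble_features",
]

FEATURE_MODES = ("ratio", "oav_z", "combined")


def enumerate_pairs(
    odors: Mapping[str, Sequence[str]], compounds: Sequence[str]
) -> list[tuple[str, str]]:
    """All ordered compound pairs whose descriptor sets differ.

    Pairs (a, b) with a ≠ b are emitted in both orientations; pairs of
    compounds carrying *identical* descriptor sets are excluded (their ratio
    says nothing about balance between different odors).  Compounds missing
    from the odor map are skipped.
    """
    mapped = [c for c in compounds if c in odors]
    dsets = {c: frozenset(odors[c]) for c in mapped}
    return [
        (a, b)
        for a in mapped
        for b in mapped
        if a != b and dsets[a] != dsets[b]
    ]


def _log_ratio_frame(
    numerators: pd.DataFrame,
    denominators: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    max_missing: float,
) -> pd.DataFrame:
    cols = {}
    for a, b in pairs:
        num = numerators[a].to_numpy(dtype=float)
        den = denominators[b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where((num > 0) & (den > 0), np.log2(num / den), np.nan)
        cols[f"{a}/{b}"] = vals
    out = pd.DataFrame(cols, index=numerators.index)
    if out.empty:
        return out
    n = len(out.index)
    keep = out.columns[out.isna().sum(axis=0) <= max_missing * n]
    out = out[keep]
    return out.fillna(out.median(axis=0))


def compute_log_ratios(
    oav: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Samples × features matrix of log2(OAV_a / OAV_b) for the given pairs.

    Non-positive operands yield a missing value; features missing in more
    than ``max_missing`` of samples are dropped, remaining gaps are filled
    with the feature median.  Feature ids are ``"a/b"``.
    """
    unknown = {c for p in pairs for c in p if c not in oav.columns}
    if unknown:
        raise ValidationError(f"pairs reference unknown compounds: {sorted(unknown)}")
    return _log_ratio_frame(oav, oav, pairs, max_missing)


def compute_descriptor_ratios(
    oav_sum: pd.DataFrame, max_missing: float = 0.5
) -> pd.DataFrame:
    """Log2 ratios of accumulated OAVs over all ordered descriptor pairs."""
    descriptors = list(oav_sum.columns)
    pairs = [(a, b) for a in descriptors for b in descriptors if a != b]
    return _log_ratio_frame(oav_sum, oav_sum, pairs, max_missing)


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    x = frame.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (x - mu) / sd


def assemble_features(
    oav: pd.DataFrame,
    oav_sum: pd.DataFrame,
    odors: Mapping[str, Sequence[str]],
    mode: str = "ratio",
    max_missing: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a classifier input matrix in one of three modes.

    ``ratio``     compound-level cross-descriptor-set ratios plus
                  descriptor-level ratios;
    ``oav_z``     per-compound z-scored OAVs (population sd convention,
                  so each column has mean 0 and sd exactly 1);
    ``combined``  the union of both.

    Returns the feature matrix and a metadata frame with columns
    ``feature``, ``level`` (compound_ratio / descriptor_ratio / oav_z),
    ``numerator``, ``denominator``.
    """
    if mode not in FEATURE_MODES:
        raise ValidationError(f"unknown feature mode '{mode}' (choose from {FEATURE_MODES})")
    if not oav.index.equals(oav_sum.index):
        raise ValidationError("OAV and accumulated-OAV matrices cover different samples")

    blocks: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    if mode in ("ratio", "combined"):
        pairs = enumerate_pairs(odors, list(oav.columns))
        compound_ratios = compute_log_ratios(oav, pairs, max_missing=max_missing)
        descriptor_ratios = compute_descriptor_ratios(oav_sum, max_missing=max_missing)
        blocks += [compound_ratios, descriptor_ratios]
        meta_rows += [
            {"feature": f, "level": "compound_ratio",
             "numerator": f.split("/")[0], "denominator": f.split("/")[1]}
            for f in compound_ratios.columns
        ]
        meta_rows += [
            {"feature": f, "level": "descriptor_ratio",
             "numerator": f.split("/")[0], "denominator": f.split("/")[1]}
            for f in descriptor_ratios.columns
        ]
    if mode in ("oav_z", "combined"):
        z = _zscore(oav.fillna(0.0))
        blocks.append(z)
        meta_rows += [
            {"feature": c, "level": "oav_z", "numerator": c, "denominator": ""}
            for c in z.columns
        ]
    features = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(meta_rows, columns=["feature", "level", "numerator", "denominator"])
    return features, meta
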