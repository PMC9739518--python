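"""Synthetic two-group spirit cohorts.

Real graded-spirit concentration tables are rarely public, so the package
ships a generator that reproduces the statistical structure the pipeline
assumes: per-compound, per-group log-normal odor activity values with
moments matched to the packaged reference table (default cohort: 39
"relatively good" vs 27 "relatively poor" samples over 41 compounds),
optional planted correlation blocks imposed through a Gaussian copula, and
optional planted log2-ratio effects between groups.  OAVs are converted to
concentrations by multiplying each compound's odor threshold, so a round
trip through the OAV engine recovers the generated values.

Log-normal marginals are the natural choice here: concentrations are
positive and right-skewed, and several reference compounds have a standard
deviation exceeding the mean, which a log-normal accommodates.  Moments are
matched in arithmetic (not log) space: for target mean m and sd s,
``σ² = ln(1 + s²/m²)`` and ``μ = ln m − σ²/2``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .exceptions import ValidationError

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "plant_ratio_effect",
    "spec_from_yaml",
    "spec_to_yaml",
]


@dataclass
class CohortSpec:
    """Everything needed to generate a two-group synthetic cohort.

    ``moments`` is a compounds × {mean_<g>, std_<g>} frame for the two group
    labels; ``correlation_blocks`` are (compound tuple, pairwise ρ) pairs
    imposed within *both* groups; ``ratio_effects`` are ((numerator,
    denominator), log2 shift) pairs scaling the numerator in the *second*
    group; ``zero_probability`` injects below-LOD zeros independently per
    cell after correlation imposition.
    """

    moments: pd.DataFrame
    thresholds: pd.Series
    odor_map: dict[str, tuple[str, ...]]
    group_labels: tuple[str, str] = ("RG", "RP")
    group_sizes: tuple[int, int] = (39, 27)
    correlation_blocks: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    ratio_effects: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    zero_probability: float = 0.0

    @property
    def compounds(self) -> list[str]:
        return list(self.moments.index)

    def validate(self) -> None:
        for g, n in zip(self.group_labels, self.group_sizes):
            if n < 3:
                raise ValidationError(f"group '{g}' size {n} < 3")
        for g in self.group_labels:
            for col in (f"mean_{g}", f"std_{g}"):
                if col not in self.moments.columns:
                    raise ValidationError(f"moments frame lacks column '{col}'")
                if (self.moments[col] < 0).any():
                    raise ValidationError(f"negative entries in '{col}'")
            if (self.moments[f"mean_{g}"] <= 0).any():
                bad = self.moments.index[self.moments[f"mean_{g}"] <= 0]
                raise ValidationError(f"non-positive mean OAV for: {', '.join(bad)}")
        missing = [c for c in self.compounds if c not in self.thresholds.index]
        if missing:
            raise ValidationError(f"compounds without thresholds: {', '.join(missing)}")
        if not 0.0 <= self.zero_probability < 1.0:
            raise ValidationError("zero_probability must be in [0, 1)")
        for members, rho in self.correlation_blocks:
            unknown = [c for c in members if c not in self.compounds]
            if unknown:
                raise ValidationError(f"correlation block names unknown compounds: {unknown}")
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"block ρ={rho} outside (−1, 1)")
        for (a, b), _shift in self.ratio_effects:
            for c in (a, b):
                if c not in self.compounds:
                    raise ValidationError(f"ratio effect names unknown compound '{c}'")


def default_cohort_spec() -> CohortSpec:
    """Cohort spec seeded from the packaged 41-compound reference table."""
    return CohortSpec(
        moments=datasets.reference_oav_summary(),
        thresholds=datasets.reference_thresholds(),
        odor_map=datasets.reference_odor_map(),
    )


def _correlation_matrix(spec: CohortSpec) -> np.ndarray:
    p = len(spec.compounds)
    idx = {c: i for i, c in enumerate(spec.compounds)}
    corr = np.eye(p)
    for members, rho in spec.correlation_blocks:
        ids = [idx[c] for c in members]
        for i in ids:
            for j in ids:
                if i != j:
                    corr[i, j] = rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        blocks = "; ".join(
            "(" + ", ".join(m) + f") rho={r}" for m, r in spec.correlation_blocks
        )
        raise ValidationError(
            f"correlation structure not positive definite (blocks: {blocks})"
        ) from exc
    return corr


def _lognormal_params(mean: np.ndarray, std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cv2 = np.where(mean > 0, (std / mean) ** 2, 0.0)
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_cohort(spec: CohortSpec, seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Draw one cohort: a samples × compounds concentration table (μg/L) and
    group labels.

    Per group, latent standard normals are drawn from the block correlation
    structure (Gaussian copula), mapped through each compound's log-normal
    marginal, multiplied by the compound's threshold to become a
    concentration, then zeroed independently with ``zero_probability``.
    Identical spec + seed always yields an identical cohort.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    corr = _correlation_matrix(spec)
    chol = np.linalg.cholesky(corr)
    compounds = spec.compounds
    thresholds = spec.thresholds.loc[compounds].to_numpy(dtype=float)

    frames = []
    labels: dict[str, str] = {}
    for gi, (g, n) in enumerate(zip(spec.group_labels, spec.group_sizes)):
        mean = spec.moments[f"mean_{g}"].to_numpy(dtype=float).copy()
        std = spec.moments[f"std_{g}"].to_numpy(dtype=float).copy()
        if gi == 1:
            # planted ratio effects scale the numerator in the second group,
            # mean and sd together so the log-space shift is exact
            for (a, _b), shift in spec.ratio_effects:
                ia = compounds.index(a)
                mean[ia] *= 2.0**shift
                std[ia] *= 2.0**shift
        mu, sigma = _lognormal_params(mean, std)
        z = rng.standard_normal((n, len(compounds))) @ chol.T
        oav = np.exp(mu + sigma * z)
        if spec.zero_probability > 0:
            mask = rng.random(oav.shape) < spec.zero_probability
            oav = np.where(mask, 0.0, oav)
        conc = oav * thresholds
        names = [f"{g}_{i + 1:03d}" for i in range(n)]
        frames.append(pd.DataFrame(conc, index=names, columns=compounds))
        labels.update({s: g for s in names})
    quant = pd.concat(frames, axis=0)
    groups = pd.Series(labels, name="group").loc[quant.index]
    return quant, groups


def plant_ratio_effect(
    spec: CohortSpec, pair: tuple[str, str], log2_shift: float
) -> CohortSpec:
    """Return a copy of *spec* with a planted log2-ratio effect.

    The numerator's second-group distribution is scaled by 2^shift (mean and
    sd together, preserving its coefficient of variation), so the expected
    between-group difference in log2(OAV_num / OAV_den) equals exactly the
    shift.  A shift of 0 returns an equivalent spec.
    """
    for c in pair:
        if c not in spec.compounds:
            raise ValidationError(f"unknown compound '{c}' in ratio effect")
    out = copy.deepcopy(spec)
    if log2_shift != 0:
        out.ratio_effects = list(out.ratio_effects) + [((pair[0], pair[1]), float(log2_shift))]
    return out


# ---------------------------------------------------------------------------
# YAML round trip for the CLI


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    payload = {
        "group_labels": list(spec.group_labels),
        "group_sizes": list(spec.group_sizes),
        "zero_probability": float(spec.zero_probability),
        "compounds": {
            c: {
                "threshold_ug_per_L": float(spec.thresholds[c]),
                "descriptors": list(spec.odor_map.get(c, ())),
                **{
                    f"{stat}_{g}": float(spec.moments.loc[c, f"{stat}_{g}"])
                    for g in spec.group_labels
                    for stat in ("mean", "std")
                },
            }
            for c in spec.compounds
        },
        "correlation_blocks": [
            {"compounds": list(members), "rho": float(rho)}
            for members, rho in spec.correlation_blocks
        ],
        "ratio_effects": [
            {"numerator": a, "denominator": b, "log2_shift": float(s)}
            for (a, b), s in spec.ratio_effects
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    labels = tuple(payload["group_labels"])
    comp = payload["compounds"]
    compounds = list(comp)
    moments = pd.DataFrame(
        {
            f"{stat}_{g}": [float(comp[c][f"{stat}_{g}"]) for c in compounds]
            for g in labels
            for stat in ("mean", "std")
        },
        index=compounds,
    )
    thresholds = pd.Series(
        [float(comp[c]["threshold_ug_per_L"]) for c in compounds], index=compounds,
        name="threshold_ug_per_L",
    )
    odor_map = {c: tuple(comp[c].get("descriptors", ())) for c in compounds}
    odor_map = {c: d for c, d in odor_map.items() if d}
    return CohortSpec(
        moments=moments,
        thresholds=thresholds,
        odor_map=odor_map,
        group_labels=labels,  # type: ignore[arg-type]
        group_sizes=tuple(payload["group_sizes"]),  # type: ignore[arg-type]
        correlation_blocks=[
            (tuple(b["compounds"]), float(b["rho"]))
            for b in payload.get("correlation_blocks", [])
        ],
        ratio_effects=[
            ((e["numerator"], e["denominator"]), float(e["log2_shift"]))
            for e in payload.get("ratio_effects", [])
        ],
        zero_probability=float(payload.get("zero_probability", 0.0)),
    )
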