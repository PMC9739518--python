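"""Two-group screening statistics and ordination.

The screening statistic throughout is the Kruskal–Wallis rank test (with two
groups it is equivalent to a two-sided Mann–Whitney test), with tie
correction and a chi-square reference distribution on one degree of freedom.
Significance is the raw p < alpha rule; a Benjamini–Hochberg option exists
but is off by default, matching the uncorrected screening convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.decomposition import PCA as _PCA

from .exceptions import InsufficientDataError, ValidationError

__all__ = ["kruskal_wallis", "significance_screen", "pca_scores", "PCAResult"]


def kruskal_wallis(values: pd.Series | np.ndarray, groups: pd.Series) -> tuple[float, float]:
    """Kruskal–Wallis H and p-value for a two-group comparison.

    Values are matched to groups by index when *values* is a Series,
    positionally otherwise.  Degenerate inputs follow the tie-corrected
    limit: if every observation is identical, H = 0 and p = 1.

    Returns ``(nan, nan)`` when either group has fewer than two usable
    observations.
    """
    if isinstance(values, pd.Series):
        common = values.index.intersection(groups.index)
        values = values.loc[common]
        groups = groups.loc[common]
    else:
        values = pd.Series(np.asarray(values, dtype=float), index=groups.index)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need two non-empty groups")
    samples = []
    for label in labels:
        x = values[groups == label].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            return (float("nan"), float("nan"))
        samples.append(x)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return (0.0, 1.0)
    h, p = _sstats.kruskal(*samples)
    return float(h), float(p)


def significance_screen(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-variable Kruskal–Wallis screen of a samples × variables matrix.

    Returns one row per variable with the H statistic, p-value, a boolean
    ``significant`` flag at *alpha* and the ``higher_in`` group (the label
    with the larger group mean).  ``correction="bh"`` switches to
    Benjamini–Hochberg adjusted p-values; the default applies none.
    """
    labels = [l for l in pd.unique(groups) if (groups == l).any()]
    if len(labels) != 2:
        raise ValidationError(f"expected two groups, found {labels}")
    rows = []
    for var in matrix.columns:
        h, p = kruskal_wallis(matrix[var], groups)
        means = {l: matrix[var][groups[groups == l].index.intersection(matrix.index)].mean() for l in labels}
        higher = max(labels, key=lambda l: (means[l] if np.isfinite(means[l]) else -np.inf))
        rows.append({"variable": var, "H": h, "p": p, "higher_in": higher})
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy(dtype=float)
    if correction == "bh":
        adj = np.full_like(pvals, np.nan)
        ok = np.isfinite(pvals)
        adj[ok] = _sstats.false_discovery_control(pvals[ok], method="bh")
        out["p_adjusted"] = adj
        out["significant"] = adj < alpha
    elif correction is None:
        out["significant"] = pvals < alpha
    else:
        raise ValidationError(f"unknown correction '{correction}'")
    return out


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # samples × components
    loadings: pd.DataFrame        # variables × components, orthonormal
    explained_variance_ratio: np.ndarray


def pca_scores(matrix: pd.DataFrame, n_components: int = 2, scale: bool = True) -> PCAResult:
    """PCA of a samples × variables matrix.

    Variables are centred and, by default, scaled to unit variance so that
    high-abundance compounds do not dominate.  Component signs follow the
    largest-absolute-loading-positive convention so results are reproducible
    across linear-algebra backends.
    """
    if matrix.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least two variables")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
    n_components = min(n_components, min(x.shape))
    pca = _PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # variables × components
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
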