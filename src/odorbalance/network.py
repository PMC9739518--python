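"""Pearson co-abundance networks.

Variables (compounds, or odor descriptors via their accumulated OAVs) become
nodes; an edge connects a pair whose Pearson correlation across samples
exceeds a threshold in absolute value (default |r| > 0.6, with negative
edges kept and sign-annotated).  Networks can be built per quality group or
on the pooled cohort; node attributes carry per-group mean abundances so
exports render directly in Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "pearson_matrix",
    "build_network",
    "group_networks",
    "hub_degrees",
    "compare_groups",
    "pairwise_trend",
    "TrendResult",
]


def pearson_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p over a samples × variables matrix.

    Constant columns yield NaN correlations (flagged by a warning from the
    underlying computation being suppressed into NaN).  Requires ≥3 samples
    so the t-based p-value is defined.
    """
    n = len(data.index)
    if n < 3:
        raise InsufficientDataError(f"Pearson correlation needs ≥3 samples, got {n}")
    x = data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    # t-transform for two-sided p; |r|=1 -> p=0, NaN propagates
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * _sstats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, 0.0)
    cols = data.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    r: pd.DataFrame,
    node_meta: pd.DataFrame | None = None,
    p: pd.DataFrame | None = None,
    threshold: float = 0.6,
    include_negative: bool = True,
    level: str = "compound",
    group: str = "all",
    drop_isolated: bool = True,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected network.

    An edge joins an unordered pair when ``|r| > threshold`` (or
    ``r > threshold`` when negative correlations are excluded).  Edge
    attributes: ``r``, ``sign`` ("pos"/"neg"), ``p`` (when given), ``group``.
    Node attributes come from *node_meta* (rows indexed by node id); a
    numeric ``mean_<group>`` column also yields a ``log_mean_<group>`` size
    attribute (log10 of 1 + mean).  Isolated nodes are dropped by default.
    """
    if r.shape[0] != r.shape[1] or not r.index.equals(r.columns):
        raise ValidationError("correlation matrix must be square with matching labels")
    g = nx.Graph(level=level, group=group, threshold=float(threshold))
    nodes = list(r.index)
    g.add_nodes_from(nodes)
    if node_meta is not None:
        for node in nodes:
            if node in node_meta.index:
                for key, val in node_meta.loc[node].items():
                    g.nodes[node][str(key)] = val
                    if str(key).startswith("mean_") and pd.notna(val) and float(val) >= 0:
                        g.nodes[node]["log_" + str(key)] = float(np.log10(1.0 + float(val)))
    vals = r.to_numpy(dtype=float)
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            rij = vals[i, j]
            if not np.isfinite(rij):
                continue
            passes = abs(rij) > threshold if include_negative else rij > threshold
            if passes:
                b = nodes[j]
                attrs = {"r": float(rij), "sign": "pos" if rij > 0 else "neg", "group": group}
                if p is not None:
                    attrs["p"] = float(p.loc[a, b])
                g.add_edge(a, b, **attrs)
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def group_networks(
    data: pd.DataFrame,
    groups: pd.Series,
    node_meta: pd.DataFrame | None = None,
    threshold: float = 0.6,
    include_negative: bool = True,
    level: str = "compound",
    drop_isolated: bool = True,
) -> dict[str, nx.Graph]:
    """Per-group networks plus the pooled ``"all"`` network."""
    out: dict[str, nx.Graph] = {}
    subsets: list[tuple[str, pd.DataFrame]] = [("all", data)]
    for label in pd.unique(groups):
        members = [s for s in data.index if groups.get(s) == label]
        subsets.append((str(label), data.loc[members]))
    for name, block in subsets:
        r, p = pearson_matrix(block)
        out[name] = build_network(
            r, node_meta=node_meta, p=p, threshold=threshold,
            include_negative=include_negative, level=level, group=name,
            drop_isolated=drop_isolated,
        )
    return out


def hub_degrees(network: nx.Graph) -> pd.Series:
    """Node degree table, sorted descending then lexicographic (ties visible)."""
    deg = pd.Series(dict(network.degree()), dtype=int, name="degree")
    return deg.sort_index().sort_values(ascending=False, kind="stable")


def compare_groups(net_a: nx.Graph, net_b: nx.Graph) -> pd.DataFrame:
    """Per-node degree difference between two networks on a shared universe.

    Nodes absent from one network (isolated there) count as degree 0.
    """
    nodes = sorted(set(net_a.nodes) | set(net_b.nodes))
    da = dict(net_a.degree())
    db = dict(net_b.degree())
    return pd.DataFrame(
        {
            "node": nodes,
            "degree_a": [da.get(n, 0) for n in nodes],
            "degree_b": [db.get(n, 0) for n in nodes],
            "degree_diff": [da.get(n, 0) - db.get(n, 0) for n in nodes],
        }
    )


@dataclass(frozen=True)
class TrendResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def pairwise_trend(
    data: pd.DataFrame, a: str, b: str, groups: pd.Series
) -> dict[str, TrendResult | None]:
    """Per-group correlation and least-squares trend between two variables.

    For each group label, returns Pearson r, its two-sided p, and the
    coefficients of the line ``b ~ slope * a + intercept``; ``None`` when a
    variable is constant (correlation undefined) or the group has <3 samples.
    """
    for var in (a, b):
        if var not in data.columns:
            raise ValidationError(f"unknown variable '{var}'")
    out: dict[str, TrendResult | None] = {}
    for label in pd.unique(groups):
        members = [s for s in data.index if groups.get(s) == label]
        x = data.loc[members, a].to_numpy(dtype=float)
        y = data.loc[members, b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            out[str(label)] = None
            continue
        fit = _sstats.linregress(x, y)
        out[str(label)] = TrendResult(
            r=float(fit.rvalue), p=float(fit.pvalue),
            slope=float(fit.slope), intercept=float(fit.intercept), n=len(x),
        )
    return out
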