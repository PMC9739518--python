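"""Readers and writers for the four pipeline input tables and result artifacts.

All concentrations are normalised to μg/L at read time; everything downstream
assumes that unit.  In-memory containers are deliberately plain:

* quantity table  -- :class:`pandas.DataFrame`, samples as rows, compounds as
  columns, ``NaN`` marking a missing (unquantified) cell;
* odor thresholds -- :class:`pandas.Series` indexed by compound (μg/L);
* odor map        -- ``dict`` mapping compound -> tuple of normalised
  descriptor labels;
* group labels    -- :class:`pandas.Series` indexed by sample.

The module also holds the internal-standard calibration helper used to turn
GC-FID response ratios into concentration ratios, and exporters for
co-abundance networks (GraphML / SIF / edge CSV) that Cytoscape can import.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .exceptions import InsufficientDataError, TableFormatError, ValidationError

__all__ = [
    "read_quant_table",
    "write_quant_table",
    "read_threshold_table",
    "read_odor_map",
    "read_groups",
    "normalize_descriptor",
    "CalibrationCurve",
    "fit_calibration",
    "invert_calibration",
    "write_network",
    "validate_quant_table",
]

#: accepted spellings for the two supported concentration units
_UG_ALIASES = {"ug/l", "μg/l", "µg/l", "ug_per_l"}
_MG_ALIASES = {"mg/l", "mg_per_l"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
        if seen[x] == 2:
            dupes.append(x)
    if dupes:
        raise TableFormatError(f"duplicate {what} id(s): {', '.join(map(str, dupes))}")


def validate_quant_table(table: pd.DataFrame) -> None:
    """Raise unless *table* satisfies the quantity-table invariants.

    Rows are samples, columns are compounds, values non-negative μg/L
    concentrations with NaN allowed for missing cells.
    """
    _check_unique(list(table.index), "sample")
    _check_unique(list(table.columns), "compound")
    values = table.to_numpy(dtype=float)
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"negative concentration at sample '{table.index[i]}', "
            f"compound '{table.columns[j]}': {values[i, j]}"
        )


def read_quant_table(path: str | Path, unit: str = "ug/L") -> pd.DataFrame:
    """Read a samples × compounds concentration CSV.

    Parameters
    ----------
    path
        CSV with a header row of compound ids and sample ids in the first
        column.
    unit
        ``"ug/L"`` (default) or ``"mg/L"``; mg/L values are converted to μg/L
        (×1000) so the rest of the pipeline sees a single unit.

    Returns
    -------
    pandas.DataFrame
        Validated table in μg/L; empty cells become ``NaN``.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    _check_unique([str(h) for h in header[1:]], "compound")
    raw = pd.read_csv(path, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        table = raw.astype(float)
    except ValueError as exc:  # non-numeric cell
        raise TableFormatError(f"non-numeric concentration in {path}: {exc}") from exc
    key = unit.strip().lower()
    if key in _MG_ALIASES:
        table = table * 1000.0
    elif key not in _UG_ALIASES:
        raise ValidationError(f"unknown unit '{unit}' (expected ug/L or mg/L)")
    validate_quant_table(table)
    return table


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a quantity table (μg/L) so that ``read_quant_table`` round-trips."""
    table.to_csv(path, index_label="sample")


def read_threshold_table(path: str | Path) -> pd.Series:
    """Read a ``compound,threshold_ug_per_L`` CSV into a Series (μg/L).

    Thresholds must be strictly positive: an odor threshold of zero would make
    the odor activity value undefined.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected columns compound,threshold_ug_per_L")
    compounds = df.iloc[:, 0].astype(str)
    _check_unique(list(compounds), "compound")
    thresholds = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=list(compounds), name="threshold_ug_per_L")
    bad = thresholds[~(thresholds > 0)]
    if len(bad):
        raise ValidationError(f"non-positive odor threshold for: {', '.join(bad.index)}")
    return thresholds


def normalize_descriptor(label: str) -> str:
    """Normalise a free-text odor descriptor: lowercase, trimmed."""
    return " ".join(label.strip().lower().split())


def read_odor_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a ``compound,descriptors`` CSV into a compound → descriptors map.

    The descriptor cell may hold several comma-separated labels (``"Nutty,
    sweet, bread"``); labels are case-folded and trimmed.  Compounds with an
    empty descriptor cell are excluded with a warning.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected columns compound,descriptors")
    _check_unique(list(df.iloc[:, 0].astype(str)), "compound")
    odor_map: dict[str, tuple[str, ...]] = {}
    for compound, cell in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]):
        if pd.isna(cell) or not str(cell).strip():
            warnings.warn(f"compound '{compound}' has no odor descriptor; excluded from odor map")
            continue
        labels = tuple(normalize_descriptor(tok) for tok in str(cell).split(",") if tok.strip())
        odor_map[compound] = labels
    return odor_map


def read_groups(path: str | Path, samples: Iterable[str] | None = None) -> pd.Series:
    """Read a ``sample,group`` CSV into a Series of group labels.

    Exactly two distinct labels are required (the pipeline is a two-group
    comparison).  If *samples* is given, labels for unknown samples are
    dropped with a warning and every listed sample must be labelled.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected columns sample,group")
    _check_unique(list(df.iloc[:, 0].astype(str)), "sample")
    groups = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=list(df.iloc[:, 0].astype(str)), name="group"
    )
    if samples is not None:
        samples = list(samples)
        unknown = groups.index.difference(samples)
        if len(unknown):
            warnings.warn(f"group labels for unknown sample(s) ignored: {', '.join(unknown)}")
            groups = groups.drop(unknown)
        missing = pd.Index(samples).difference(groups.index)
        if len(missing):
            raise ValidationError(f"sample(s) without a group label: {', '.join(missing)}")
    labels = groups.unique()
    if len(labels) != 2:
        raise ValidationError(f"expected exactly two group labels, found {sorted(labels)}")
    return groups


# ---------------------------------------------------------------------------
# internal-standard calibration


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line mapping concentration ratio → response ratio.

    Fitted from GC-FID working standards: ``response_ratio = slope *
    concentration_ratio + intercept``, both ratios taken against the spiked
    internal standard.
    """

    compound_id: str
    slope: float
    intercept: float
    r_squared: float
    internal_standard_id: str = ""
    n_points: int = 0

    def predict(self, concentration_ratio: float) -> float:
        return self.slope * float(concentration_ratio) + self.intercept


def fit_calibration(
    points: Sequence[tuple[float, float]],
    compound_id: str = "",
    internal_standard_id: str = "",
) -> CalibrationCurve:
    """Fit a calibration line to ``(concentration ratio, response ratio)`` points.

    At least three points with distinct concentration ratios are required.
    """
    if len(points) < 3:
        raise InsufficientDataError(f"calibration needs ≥3 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < len(x):
        raise ValidationError("concentration ratios must be distinct")
    fit = _sstats.linregress(x, y)
    # a perfectly horizontal response still yields r=nan; treat as r²=1 fit of a constant
    r2 = 1.0 if np.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    return CalibrationCurve(
        compound_id=compound_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        internal_standard_id=internal_standard_id,
        n_points=len(points),
    )


def invert_calibration(curve: CalibrationCurve, response_ratio: float) -> float:
    """Concentration ratio producing *response_ratio* under *curve*."""
    if curve.slope == 0:
        raise ValidationError("cannot invert a flat calibration curve (slope 0)")
    return (float(response_ratio) - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# network export

_NETWORK_FORMATS = ("graphml", "sif", "edge-csv")


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a co-abundance network for Cytoscape.

    ``graphml`` keeps all node/edge attributes; ``sif`` writes
    ``source <sign> target`` interaction lines (isolated nodes on their own
    line); ``edge-csv`` writes one row per edge with its attributes.
    """
    fmt = format.strip().lower()
    if fmt not in _NETWORK_FORMATS:
        raise ValidationError(f"unknown network format '{format}' (choose from {_NETWORK_FORMATS})")
    path = Path(path)
    if fmt == "graphml":
        export = nx.Graph(**{k: v for k, v in network.graph.items() if v is not None})
        for node, attrs in network.nodes(data=True):
            export.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in network.edges(data=True):
            export.add_edge(u, v, **{k: w for k, w in attrs.items() if w is not None})
        nx.write_graphml(export, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            isolated = set(nx.isolates(network))
            for u, v, attrs in network.edges(data=True):
                fh.write(f"{u}\t{attrs.get('sign', 'pos')}\t{v}\n")
            for node in isolated:
                fh.write(f"{node}\n")
    else:
        rows = [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in network.edges(data=True)
        ]
        cols = ["source", "target", "r", "p", "sign", "group"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.NA
        df.to_csv(path, index=False, columns=cols)


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (round-trip helper)."""
    return nx.read_graphml(path)
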