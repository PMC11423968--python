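"""Readers and writers for the interchange formats.

Everything is tab-delimited labeled text (header row of column labels, first
column of row labels, token "NA" for missing entries) or JSON, chosen for
diffability — the matrices involved are at most a few thousand by ~60.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, binarize
from .hull import PrimacyHull
from .overlap import OdorResponseMatrix

MISSING = "NA"


def read_labeled_matrix(
    path: str | Path,
    delimiter: str = "\t",
) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Parse a labeled delimited matrix -> (values, row labels, col labels, mask).

    "NA" cells are masked (mask false) and hold 0.0 in ``values``.  Duplicate
    labels, ragged rows and non-numeric cells raise.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate column labels in {path}")
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[MISSING],
        keep_default_na=False,
    )
    if df.index.has_duplicates:
        raise ValueError(f"duplicate row labels in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    mask = ~np.isnan(values)
    values = np.nan_to_num(values, nan=0.0)
    return values, [str(i) for i in df.index], [str(c) for c in df.columns], mask


def write_labeled_matrix(
    path: str | Path,
    values: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    mask: np.ndarray | None = None,
    delimiter: str = "\t",
    float_format: str = "%.8g",
) -> None:
    """Write a labeled matrix; masked entries become "NA"."""
    values = np.asarray(values)
    df = pd.DataFrame(values, index=row_labels, columns=col_labels)
    if mask is not None:
        df = df.mask(~np.asarray(mask, dtype=bool))
    df.to_csv(path, sep=delimiter, na_rep=MISSING, float_format=float_format)


def read_edge_list(path: str | Path, threshold: int = 1) -> ConnectivityMatrix:
    """Ingest "kc_id<TAB>glomerulus<TAB>weight" into binary connectivity.

    Duplicate edges are summed before binarization.  A header line is
    tolerated if its third field is non-numeric.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["kc", "glom", "weight"])
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty edge list {path}") from exc
    if df.empty:
        raise ValueError(f"empty edge list {path}")
    first = df.iloc[0]["weight"]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
        if df.empty:
            raise ValueError(f"edge list {path} has a header but no rows")
    try:
        df["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed weight in {path}: {exc}") from exc
    if (df["weight"] < 0).any():
        raise ValueError("negative edge weight")
    pivot = df.pivot_table(index="kc", columns="glom", values="weight", aggfunc="sum", fill_value=0)
    return binarize(
        pivot.to_numpy(),
        [str(i) for i in pivot.index],
        [str(c) for c in pivot.columns],
        threshold=threshold,
    )


def read_connectivity(path: str | Path, threshold: int = 1) -> ConnectivityMatrix:
    """Read connectivity from a labeled matrix (rows = KCs, columns = glomeruli)."""
    values, kc_labels, glom_labels, mask = read_labeled_matrix(path)
    if not mask.all():
        raise ValueError("connectivity matrices may not contain missing entries")
    return binarize(values, kc_labels, glom_labels, threshold=threshold)


def write_connectivity(path: str | Path, C: ConnectivityMatrix) -> None:
    write_labeled_matrix(path, C.binary.astype(int), C.kc_labels, C.glom_labels, float_format="%d")


def read_responses(path: str | Path) -> OdorResponseMatrix:
    """Read an OR x odorant normalized response matrix with NA missingness."""
    values, or_labels, odor_labels, mask = read_labeled_matrix(path)
    return OdorResponseMatrix(values=values, or_labels=or_labels, odor_labels=odor_labels, observed=mask)


def write_responses(path: str | Path, A: OdorResponseMatrix) -> None:
    write_labeled_matrix(path, A.values, A.or_labels, A.odor_labels, mask=A.observed)


def read_glom_or_map(path: str | Path) -> pd.DataFrame:
    """Two-column glomerulus -> OR table (tab-delimited, header optional)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("glomerulus-OR map needs two columns")
    return df.iloc[:, :2]


def write_hull(path: str | Path, hull: PrimacyHull) -> None:
    Path(path).write_text(hull.to_json())


def read_hull(path: str | Path) -> PrimacyHull:
    return PrimacyHull.from_json(Path(path).read_text())


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
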