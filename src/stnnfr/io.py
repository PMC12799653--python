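"""Delimited-matrix reading and neighbor-table writing.

Training and Query matrices arrive as CSV/TSV, one observation per row,
numeric columns only, with an optional single header row (auto-detected
by default).  Neighbor output is TSV with columns query_id, rank,
train_index, distance; query_id and train_index are 1-based in the file
(0-based internally), stated in the header comment.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .search import NeighborResult

__all__ = ["read_matrix", "write_neighbors", "format_neighbors"]


def _row_is_numeric(tokens) -> bool:
    for tok in tokens:
        try:
            float(tok)
        except (TypeError, ValueError):
            return False
    return True


def read_matrix(path, header: str = "auto") -> np.ndarray:
    """Read a numeric matrix from CSV/TSV.

    ``header`` is "auto" (header row detected by non-numeric cells),
    "yes" or "no".  Missing or non-numeric data cells are an error.
    """
    if header not in ("auto", "yes", "no"):
        raise ValueError("header must be one of 'auto', 'yes', 'no'")
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                         comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    drop_first = header == "yes" or (header == "auto" and not _row_is_numeric(df.iloc[0]))
    if drop_first:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path} contains a header but no data rows")
    if df.isna().any().any():
        raise ValueError(f"{path} contains missing values")
    try:
        X = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path} contains non-numeric cells: {exc}") from exc
    if not np.isfinite(X).all():
        raise ValueError(f"{path} contains non-finite values")
    return X


def format_neighbors(result: NeighborResult) -> str:
    """Neighbor TSV as a string (atomic writes: format fully, then write)."""
    buf = _io.StringIO()
    buf.write("# query_id and train_index are 1-based\n")
    buf.write("query_id\trank\ttrain_index\tdistance\n")
    for i in range(result.n_queries):
        for rank in range(result.k):
            buf.write(
                f"{i + 1}\t{rank + 1}\t{result.indices[i, rank] + 1}\t"
                f"{result.distances[i, rank]!r}\n"
            )
    return buf.getvalue()


def write_neighbors(result: NeighborResult, path) -> None:
    text = format_neighbors(result)
    with open(path, "w") as fh:
        fh.write(text)
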