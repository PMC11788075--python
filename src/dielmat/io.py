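"""Tab-separated matrix and table IO with strict validation.

All matrices are TSV with a header row of sample labels and a first column of
feature labels; values are serialized at full precision (repr round-trip), so
write-then-read reproduces labels and values bit for bit.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled TSV matrix, validating shape, labels and cell types."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise ValueError(f"{path}: no header")
    header = lines[0].split("\t")
    ncol = len(header)
    columns = header[1:]
    if len(set(columns)) != len(columns):
        dup = next(c for c in columns if columns.count(c) > 1)
        raise ValueError(f"{path}: duplicate column label {dup!r}")
    index = []
    data = []
    for rownum, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != ncol:
            raise ValueError(
                f"{path}: row {rownum} has {len(cells)} cells, expected {ncol}"
            )
        label = cells[0]
        if label in index:
            raise ValueError(f"{path}: duplicate row label {label!r} at row {rownum}")
        index.append(label)
        row = []
        for colnum, cell in enumerate(cells[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {rownum}, column {colnum}: "
                    f"{cell!r}"
                ) from None
        data.append(row)
    return pd.DataFrame(data, index=index, columns=columns)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labeled matrix as TSV with full-precision values."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["feature", *map(str, matrix.columns)]) + "\n")
        for label, row in zip(matrix.index, matrix.to_numpy()):
            cells = [repr(float(v)) if not float(v).is_integer() else str(int(v)) for v in row]
            fh.write("\t".join([str(label), *cells]) + "\n")


def read_table(path) -> pd.DataFrame:
    """Read a TSV table of mixed (non-matrix) columns, first column as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n",
        encoding="utf-8",
    )


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
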