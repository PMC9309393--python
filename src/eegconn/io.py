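"""Serialization of connectivity and group matrices.

A matrix is written as a labeled CSV (header row and index column) plus a
JSON sidecar ``<stem>.meta.json`` recording metric, band and estimation
parameters; alternatively a single self-contained JSON file holds both.
Internal-connectivity tables are labeled two-column CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .aggregate import GroupMatrix
from .errors import FormatError
from .metrics import ConnectivityMatrix

Matrix = Union[ConnectivityMatrix, GroupMatrix]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_matrix(m: Matrix, path: str | Path) -> Path:
    """Write a matrix as labeled CSV + JSON sidecar, or one JSON file."""
    path = Path(path)
    labels = list(m.labels) if isinstance(m, ConnectivityMatrix) else list(m.groups)
    meta = {"metric": m.metric, "band": m.band, "meta": m.meta}
    if isinstance(m, GroupMatrix):
        meta["level"] = m.level
    if path.suffix == ".json":
        doc = {**meta, "labels": labels, "weights": m.weights.tolist()}
        path.write_text(json.dumps(doc, indent=1))
    else:
        pd.DataFrame(m.weights, index=labels, columns=labels).to_csv(path)
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_matrix(path: str | Path) -> Matrix:
    """Read a matrix written by :func:`save_matrix`."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        labels, weights, meta = doc["labels"], np.array(doc["weights"]), doc
    else:
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise FormatError(f"{path.name}: row and column labels differ")
        labels, weights = [str(c) for c in df.columns], df.to_numpy(dtype=float)
        sc = _sidecar(path)
        meta = json.loads(sc.read_text()) if sc.exists() else {}
    if "level" in meta and meta["level"]:
        return GroupMatrix(weights=weights, groups=tuple(labels),
                           level=meta["level"],
                           metric=meta.get("metric", "pcc"),
                           band=meta.get("band", "broadband"),
                           meta=meta.get("meta", {}))
    return ConnectivityMatrix(weights=weights, labels=tuple(labels),
                              metric=meta.get("metric", "pcc"),
                              band=meta.get("band", "broadband"),
                              meta=meta.get("meta", {}))


def save_table(series: pd.Series, path: str | Path) -> Path:
    """Write an internal-connectivity table as a labeled two-column CSV."""
    path = Path(path)
    series.rename_axis("group").to_csv(path)
    return path
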