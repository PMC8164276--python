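"""Tabular adapters for expression and label tables.

One tabular dialect is supported: tab-separated text with a header row.
Expression tables are genes x samples with a `gene_id` first column
(RSEM-style normalized counts); label tables have `sample_id` and
`class` columns.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_expression_tsv", "read_labels_tsv", "file_digest"]


class ParseError(ValueError):
    pass


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV; validates ids and values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ParseError(f"duplicate gene id {dup[0]!r} in {path}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(frame[col], errors="coerce")
            line = int(np.argmax(bad.isna().to_numpy())) + 2  # +1 header, +1 one-based
            raise ParseError(f"unparseable value in column {col!r}, line {line} of {path}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"missing value for gene {frame.index[i]!r} (line {i + 2}), sample {frame.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"negative value for gene {frame.index[i]!r} (line {i + 2}), sample {frame.columns[j]!r}"
        )
    return pd.DataFrame(values, index=frame.index.rename("gene_id"), columns=frame.columns)


def read_labels_tsv(path: str | Path, expression: pd.DataFrame) -> pd.Series:
    """Read sample labels; every expression sample must be labelled exactly once."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in frame.columns:
            raise ParseError(f"labels file {path} lacks a {col!r} column")
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if len(dup):
        raise ParseError(f"sample {dup.iloc[0]!r} labelled more than once in {path}")
    labels = pd.Series(frame["class"].values, index=frame["sample_id"].values, name="class")
    missing = [s for s in expression.columns if s not in labels.index]
    if missing:
        raise ParseError(f"sample {missing[0]!r} has no label in {path}")
    extra = [s for s in labels.index if s not in set(expression.columns)]
    if extra:
        warnings.warn(f"{len(extra)} labelled samples absent from the expression matrix; ignored",
                      stacklevel=2)
        labels = labels.drop(index=extra)
    return labels.loc[list(expression.columns)]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
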