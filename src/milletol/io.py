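"""Delimited-text I/O helpers shared by the analysis drivers.

Delimiter is auto-detected from the extension (.csv comma, .tsv/.txt tab).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import SchemaError


def _sep(path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    """Feature x sample matrix with feature ids in the first column."""
    return pd.read_csv(path, sep=_sep(path), index_col=index_col)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep=_sep(path), index_label=index_label)


def read_sample_sheet(path) -> pd.Series:
    """Sample sheet (sample, group[, qc]) -> group Series indexed by sample."""
    sheet = pd.read_csv(path, sep=_sep(path))
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise SchemaError(f"sample sheet missing column {col!r}")
    return sheet.set_index("sample")["group"]


def read_lengths(path) -> pd.Series:
    """Two-column (gene id, length bp) file -> length Series."""
    tab = pd.read_csv(path, sep=_sep(path))
    if tab.shape[1] < 2:
        raise SchemaError("lengths file needs two columns: id, length")
    return tab.set_index(tab.columns[0])[tab.columns[1]]


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype table (variety, indicator, condition, replicate, value)."""
    return pd.read_csv(path, sep=_sep(path))
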