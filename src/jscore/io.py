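"""Reading label tables and similarity matrices; writing score reports.

Label-pair files are two-column TSV/CSV (true class, cluster assignment), one
row per sample, optional header.  Similarity tables are CSV with class labels
as the row index and cluster labels as the column header.  The delimiter is
inferred from the extension (``.tsv``/``.tab`` -> tab, otherwise comma) unless
given explicitly — no content sniffing, to avoid silent misreads.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import LabelPair

__all__ = ["read_label_pair", "read_similarity_table", "write_json"]


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_label_pair(
    path: str | Path, delimiter: str | None = None, header: bool = False
) -> LabelPair:
    """Read a two-column (true, cluster) label file into a LabelPair.

    ``header=True`` skips the first row.  Rows with a missing field are
    reported with their 1-based line number rather than dropped.
    """
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path, delimiter),
        header=0 if header else None,
        dtype=str,
        skip_blank_lines=True,
        keep_default_na=False,
    )
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    offset = 2 if header else 1
    for i, row in enumerate(df.itertuples(index=False)):
        if any(str(x).strip() == "" for x in row):
            raise ValueError(f"{path}: missing label on line {i + offset}")
    return LabelPair.from_dataframe(df)


def read_similarity_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labelled class-by-cluster similarity matrix (first column = index)."""
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty similarity table")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in similarity table: {exc}") from exc
    return values


def write_json(obj: dict, path: str | Path | None) -> str:
    """Serialise to pretty JSON; write to ``path`` unless it is None/'-'."""
    text = json.dumps(obj, indent=2, sort_keys=False, default=float)
    if path is not None and str(path) != "-":
        Path(path).write_text(text + "\n")
    return text
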