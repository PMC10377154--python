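"""Tab-separated input/output for expression, metadata and results tables.

Conventions follow GEO series-matrix style downstream users already
have: UTF-8 TSV, ``NA`` as the missing marker, the gene column named
``gene_id``; metadata columns ``sample``, ``group`` and ``time`` (or
``days``, log2-transformed on request — developmental analyses use
time = log2 of post-conceptional days). Results files carry their run
metadata as leading ``#`` comment lines and numbers at 9 significant
digits so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "read_metadata",
    "validate_tables",
    "write_expression",
    "write_metadata",
    "write_results",
    "read_results",
]

NA_VALUES = ["NA"]
FLOAT_FORMAT = "%.9g"


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=NA_VALUES, keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise ValueError(
            f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene identifiers: {sorted(set(dupes))}")
    df = df.set_index("gene_id")
    dup_cols = [c for c in df.columns[df.columns.duplicated()]]
    if dup_cols:
        raise ValueError(f"{path}: duplicate sample identifiers: {sorted(set(dup_cols))}")
    bad = []
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad.append(c)
    if bad:
        raise ValueError(f"{path}: non-numeric cells in columns: {bad}")
    return df


def read_metadata(path, log2_days: bool = False) -> pd.DataFrame:
    """Read sample metadata (columns sample, group, time | days).

    With ``log2_days`` the ``days`` column is converted to
    time = log2(days).
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=NA_VALUES, keep_default_na=False)
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: metadata needs 'sample' and 'group' columns")
    dupes = df["sample"][df["sample"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample identifiers: {sorted(set(dupes))}")
    if log2_days:
        if "days" not in df.columns:
            raise ValueError(f"{path}: --log2-days requires a 'days' column")
        days = pd.to_numeric(df["days"])
        if (days <= 0).any():
            raise ValueError(f"{path}: 'days' must be positive for log2 transform")
        df["time"] = np.log2(days)
    if "time" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'time' column (or 'days' with log2_days)")
    df["time"] = pd.to_numeric(df["time"])
    if not np.all(np.isfinite(df["time"].to_numpy())):
        bad = df.loc[~np.isfinite(df["time"].to_numpy()), "sample"].tolist()
        raise ValueError(f"{path}: non-finite times for samples: {bad}")
    return df.set_index("sample")


def validate_tables(expression: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Cross-check that expression columns and metadata samples agree."""
    expr_samples = set(expression.columns)
    meta_samples = set(metadata.index)
    orphans = sorted(expr_samples - meta_samples)
    extra = sorted(meta_samples - expr_samples)
    msgs = []
    if orphans:
        msgs.append(f"expression samples without metadata: {orphans}")
    if extra:
        msgs.append(f"metadata samples without expression: {extra}")
    if msgs:
        raise ValueError("; ".join(msgs))


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def write_metadata(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def write_results(frame: pd.DataFrame, path, run_metadata: dict | None = None) -> None:
    """Write a results table with ``#``-prefixed run-metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (run_metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=NA_VALUES, keep_default_na=False)
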