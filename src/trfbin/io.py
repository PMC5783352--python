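"""Tabular I/O: sample sheets, factor tables and sample-group summaries."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ParseError, ValidationError


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet indexed by ``sample_id``.

    Any further columns (group, strain, sex, stage, treatment, replicate,
    path, ...) are carried through as metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_ids in sample sheet: {dups}")
    return df.set_index("sample_id")


def write_factors(factors, path) -> None:
    s = factors.as_series()
    out = s.to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_group_read_table(path) -> pd.DataFrame:
    """Read a sample-group read-count table (first column: group name;
    last numeric column: read counts)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least a group and a read-count column")
    return df


def summarize_sample_groups(
    table: pd.DataFrame,
    n_libraries: Optional[int] = None,
    group_col: Optional[str] = None,
    reads_col: Optional[str] = None,
) -> dict:
    """Aggregate per-group read counts into totals.

    Returns the per-group totals, the grand total, and — when the number
    of libraries is given — the mean reads per library.  By default the
    first column names the group and the last numeric column holds the
    counts.
    """
    if group_col is None:
        group_col = table.columns[0]
    if reads_col is None:
        numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        if not numeric:
            raise ValidationError("no numeric read-count column found")
        reads_col = numeric[-1]
    totals = table.groupby(group_col, sort=False)[reads_col].sum()
    grand = int(totals.sum())
    out = {
        "group_totals": {str(k): int(v) for k, v in totals.items()},
        "n_groups": int(totals.size),
        "grand_total": grand,
        "n_libraries": n_libraries,
        "mean_reads_per_library": (grand / n_libraries) if n_libraries else None,
    }
    return out
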