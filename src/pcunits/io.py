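"""Shared table I/O: schema-checked TSV readers and writers.

All pipeline artifacts are plain TSV with a header row (matrices carry the
variable ids as first row and column).  Readers validate the declared
schema and report offending column and row numbers; unknown extra columns
are preserved with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dyncorr import DynCorrResult, ReplicatedTimeSeries

__all__ = [
    "read_table",
    "write_table",
    "read_series_tsv",
    "write_series_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

SERIES_SCHEMA = {
    "variable_id": str,
    "layer": str,
    "replicate": int,
    "time_h": float,
    "value": float,
}


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """TSV with header; coerce and validate ``schema`` columns.

    Schema violations raise with the 1-based data row number; extra columns
    pass through with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: preserving unknown columns {extra}")
    for col, typ in schema.items():
        if typ is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r}, row {bad[0] + 1}: "
                f"non-numeric value {df.loc[bad[0], col]!r}"
            )
        df[col] = coerced.astype(typ)
    return df


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_series_tsv(path, series: list[ReplicatedTimeSeries]) -> None:
    """Long format: variable_id, layer, replicate, time_h, value."""
    rows = []
    for s in series:
        for r in range(s.n_replicates):
            for k, t in enumerate(s.grid):
                rows.append((s.variable, s.layer, r + 1, t, s.values[r, k]))
    write_table(path, pd.DataFrame(rows, columns=list(SERIES_SCHEMA)))


def read_series_tsv(path) -> list[ReplicatedTimeSeries]:
    df = read_table(path, SERIES_SCHEMA)
    out = []
    for (var, layer), grp in df.groupby(["variable_id", "layer"], sort=True):
        piv = grp.pivot_table(index="replicate", columns="time_h", values="value")
        if piv.isna().any().any():
            raise ValueError(f"{path}: variable {var}: replicates disagree on time grid")
        out.append(
            ReplicatedTimeSeries(
                str(var), piv.columns.to_numpy(float), piv.to_numpy(float), str(layer)
            )
        )
    return out


def write_matrix_tsv(path, ids: list[str], M: np.ndarray) -> None:
    df = pd.DataFrame(M, index=ids, columns=ids)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column ids disagree")
    return list(df.columns), df.to_numpy(float)


def result_to_frames(dc: DynCorrResult) -> dict[str, pd.DataFrame]:
    """Correlation result as writable frames (R, Sigma, per-variable stats)."""
    stats = pd.DataFrame(
        {
            "variable_id": dc.ids,
            "variance": dc.variances,
            "grand_mean": dc.grand_means,
            "layer": [dc.layers.get(v, "") for v in dc.ids],
        }
    )
    return {
        "R": pd.DataFrame(dc.R, index=dc.ids, columns=dc.ids),
        "Sigma": pd.DataFrame(dc.Sigma, index=dc.ids, columns=dc.ids),
        "stats": stats,
    }
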