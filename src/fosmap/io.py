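"""CSV readers/writers for the pipeline's tabular formats.

All files are UTF-8 comma-separated with a single header row; the first
column is the id column. Values round-trip exactly through write/read.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .core import (
    AnimalDesign,
    BehaviorTable,
    ConnectivityMatrix,
    CountMatrix,
    ValidationError,
    design_frame,
    validate_design,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_behavior",
    "write_behavior",
    "read_connectivity",
    "write_connectivity",
]


def _read_indexed(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_counts(path) -> CountMatrix:
    df = _read_indexed(path)
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path) -> None:
    counts.df.to_csv(path, index_label="animal_id")


def read_design(path) -> list[AnimalDesign]:
    df = pd.read_csv(path, dtype=str)
    required = {"animal_id", "sex", "partner", "timepoint", "block", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    rows = [
        AnimalDesign(
            animal_id=str(r.animal_id),
            sex=str(r.sex),
            partner=str(r.partner),
            timepoint=int(r.timepoint),
            block=int(r.block),
            pair_id=str(r.pair_id),
        )
        for r in df.itertuples()
    ]
    validate_design(rows)
    return rows


def write_design(rows: list[AnimalDesign], path) -> None:
    design_frame(rows).to_csv(path, index_label="animal_id")


def read_behavior(path, levels: Mapping[str, str] | None = None) -> BehaviorTable:
    df = _read_indexed(path).astype(float)
    return BehaviorTable(df, dict(levels or {}))


def write_behavior(table: BehaviorTable, path) -> None:
    table.df.to_csv(path, index_label="unit_id")


def read_connectivity(path) -> ConnectivityMatrix:
    df = _read_indexed(path).astype(float)
    return ConnectivityMatrix(df)


def write_connectivity(conn: ConnectivityMatrix, path) -> None:
    conn.df.to_csv(path, index_label="origin_id")
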