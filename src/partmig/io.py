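"""CSV reading/writing for replicate and aggregate tables.

Schemas are versioned in a leading comment line so downstream readers can
detect format changes; missing values (undefined borders) are written as
empty fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

ZONE_HEADER = "# partmig zone-table v1: one row per recorded generation"
PERX_HEADER = "# partmig per-x-table v1: one row per (generation, x-column)"
AGG_HEADER = "# partmig aggregate-table v1: across-replicate mean/sd/n per generation"

ZONE_COLUMNS = [
    "generation",
    "polar_border",
    "equatorial_border",
    "width",
    "midpoint",
    "range_front",
    "n_total",
    "n_migrants",
    "n_residents",
]
PERX_COLUMNS = ["generation", "x", "n_migrants", "n_residents", "mean_T"]


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, na_rep="")


def write_zone_csv(df: pd.DataFrame, path) -> None:
    _write(df[ZONE_COLUMNS], Path(path), ZONE_HEADER)


def write_perx_csv(df: pd.DataFrame, path) -> None:
    _write(df[PERX_COLUMNS], Path(path), PERX_HEADER)


def write_aggregate_csv(df: pd.DataFrame, path) -> None:
    _write(df, Path(path), AGG_HEADER)


def read_table_csv(path) -> pd.DataFrame:
    """Read any partmig CSV (comment lines are skipped)."""
    return pd.read_csv(path, comment="#")


def read_zone_csvs(paths: Sequence) -> list[pd.DataFrame]:
    return [read_table_csv(p) for p in paths]
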