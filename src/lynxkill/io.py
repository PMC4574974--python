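"""CSV schemas and readers/writers shared across modules.

All tables are plain CSV with ISO-8601 timestamps, timezone-naive under a CET
convention (matching the collar protocol).  Coordinates are projected meters.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FIXES_COLUMNS = ["lynx_id", "timestamp", "x_m", "y_m"]
KILLS_COLUMNS = ["lynx_id", "status", "species", "kill_date", "left_date",
                 "x_m", "y_m", "found"]
GRID_COLUMNS = ["quad_id", "cx_m", "cy_m", "forest", "altitude_m",
                "dist_civ_m", "in_np"]
INTERVALS_COLUMNS = ["lynx_id", "status", "species", "season",
                     "handling_time", "searching_time", "prey_time",
                     "event", "involves_virtual"]


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")


def read_fixes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _check_columns(df, FIXES_COLUMNS, "fixes table")
    return df


def read_kills(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["kill_date", "left_date"])
    _check_columns(df, KILLS_COLUMNS, "kills table")
    return df


def read_grid(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GRID_COLUMNS, "grid table")
    return df


def read_intervals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, INTERVALS_COLUMNS, "intervals table")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                columns: list[str] | None = None) -> Path:
    """Write a CSV, optionally enforcing a column schema on the way out."""
    path = Path(path)
    if columns is not None:
        _check_columns(df, columns, str(path.name))
        df = df[columns]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
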