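"""CSV reading and writing for the pipeline's plain-text tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .series import DailySeries

__all__ = [
    "write_dataset",
    "read_long_table",
    "series_by_year",
    "write_table",
]

_TABLE_FILES = {
    "temperature": "temperature.csv",
    "catches": "catches.csv",
    "zooplankton": "zooplankton.csv",
    "yearly": "yearly.csv",
}


def write_dataset(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write the simulated tables to their standard CSV file names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, df in tables.items():
        path = outdir / _TABLE_FILES.get(key, f"{key}.csv")
        df.to_csv(path, index=False)
        written.append(path)
    return written


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read a (year, doy, value) long table written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    expected = {"year", "doy"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns year, doy, <value>")
    return df


def series_by_year(
    df: pd.DataFrame, value_col: str, bin_width: float = 1.0
) -> dict[int, DailySeries]:
    """Split a long (year, doy, value) table into per-year series."""
    out = {}
    for year, grp in df.groupby("year"):
        grp = grp.sort_values("doy")
        out[int(year)] = DailySeries(
            int(year), grp["doy"].to_numpy(), grp[value_col].to_numpy(),
            bin_width=bin_width,
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
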