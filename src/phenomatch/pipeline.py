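"""End-to-end assembly: raw tables -> phenology -> mismatch -> year records.

This is the glue that turns the four input tables (daily temperature,
weekly spawner catches, zooplankton counts, yearly covariates) into the
per-year record frame the recruitment model consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hatchmatch import DegreeDayParams, NoHatchError, hatch_phenology, mismatch_index
from .io import series_by_year
from .phenology import PhenologyError, fit_normal_phenology
from .series import PhenologyEstimate

__all__ = ["mismatch_table", "build_year_records"]


def mismatch_table(
    temperature: pd.DataFrame,
    catches: pd.DataFrame,
    zooplankton: pd.DataFrame,
    degree_days: DegreeDayParams = DegreeDayParams(),
    catch_bin_width: float = 7.0,
) -> pd.DataFrame:
    """Per-year hatching phenology and match/mismatch index.

    Fits the spawning curve to weekly catches (grouped likelihood), the
    zooplankton curve to sampled counts (least squares on point samples),
    propagates spawning through the degree-day model, and differences the
    peaks.  Years where any stage fails carry a reason in ``flag`` and
    NaN estimates.
    """
    temps = series_by_year(temperature, "temp_c")
    spawn = series_by_year(catches, "count", bin_width=catch_bin_width)
    zoop = series_by_year(zooplankton, "count")
    rows = []
    for year in sorted(set(spawn) & set(zoop) & set(temps)):
        row = {"year": year, "hatch_peak_doy": np.nan, "hatch_duration_days": np.nan,
               "zoop_peak_doy": np.nan, "pm_days": np.nan, "flag": "ok"}
        try:
            sfit = fit_normal_phenology(spawn[year])
            zfit = fit_normal_phenology(zoop[year], method="curve-least-squares")
            hatch = hatch_phenology(sfit, temps[year], degree_days)
            pm = mismatch_index(hatch, zfit)
            row.update(
                hatch_peak_doy=hatch.peak,
                hatch_duration_days=hatch.duration,
                zoop_peak_doy=zfit.mu,
                pm_days=pm.pm,
            )
        except (PhenologyError, NoHatchError, ValueError) as exc:
            row["flag"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def build_year_records(
    yearly: pd.DataFrame, mismatch: pd.DataFrame
) -> pd.DataFrame:
    """Merge yearly covariates with mismatch estimates into model records.

    Output columns follow the model schema: S (spawners), CA (age-3+),
    WT (winter temperature), P (disease flag), MS (mean spawner size),
    PM, LS and R (recruits), indexed by spawn year.  Flagged mismatch
    years are dropped with their flags preserved in ``attrs``.
    """
    ok = mismatch[mismatch["flag"] == "ok"]
    merged = yearly.merge(ok, on="year", how="inner")
    columns = {
        "S": "spawners",
        "MS": "mean_size_mm",
        "CA": "age3plus",
        "WT": "winter_temp_c",
        "P": "disease",
        "PM": "pm_days",
        "LS": "hatch_duration_days",
        "R": "recruits",
    }
    records = pd.DataFrame(
        {out: merged[src].to_numpy() for out, src in columns.items()},
        index=pd.Index(merged["year"].to_numpy(), name="year"),
    )
    dropped = mismatch.loc[mismatch["flag"] != "ok", ["year", "flag"]]
    records.attrs["dropped_years"] = dropped.to_dict("records")
    return records
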