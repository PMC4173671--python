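"""Sliding-window coefficient of variation of a yearly abundance series.

Population variability is summarised as the CV (sample standard
deviation over mean) computed in every window of w consecutive years,
for w = 3..11, separately for the periods before and after an age-size
truncation event.  The split year itself belongs to the post period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CVResult", "sliding_cv", "cv_table"]

DEFAULT_WINDOWS = tuple(range(3, 12))


@dataclass(frozen=True)
class CVResult:
    """Mean and s.e. of the window CVs for one (period, window) pair.

    ``mean_cv`` is NaN with ``n_windows == 0`` when the period is shorter
    than the window; the pair is flagged rather than fabricated.
    """

    period: str  # "pre" or "post"
    window: int
    mean_cv: float
    se_cv: float
    n_windows: int

    def __post_init__(self) -> None:
        if not (3 <= self.window <= 11):
            raise ValueError("window length must be in 3..11")
        if self.n_windows > 0 and self.mean_cv < 0:
            raise ValueError("CV cannot be negative")


def _window_cvs(values: np.ndarray, w: int) -> np.ndarray:
    n = len(values)
    if n < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(values, w)
    return windows.std(axis=1, ddof=1) / windows.mean(axis=1)


def sliding_cv(
    abundance: pd.Series,
    split_year: int,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
) -> list[CVResult]:
    """Sliding-window CV by period around a truncation year.

    ``abundance`` is a positive yearly series indexed by year; years
    before ``split_year`` form the pre period, the split year and later
    years the post period.  For each period and window length the CV is
    computed in every window position; the mean and its standard error
    across positions are returned.
    """
    vals = abundance.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("abundance must be positive everywhere")
    years = np.asarray(abundance.index, dtype=int)
    periods = {"pre": vals[years < split_year], "post": vals[years >= split_year]}
    out = []
    for period, pvals in periods.items():
        for w in windows:
            cvs = _window_cvs(pvals, w)
            if len(cvs) == 0:
                out.append(CVResult(period, w, float("nan"), float("nan"), 0))
            else:
                se = float(cvs.std(ddof=1) / np.sqrt(len(cvs))) if len(cvs) > 1 else 0.0
                out.append(CVResult(period, w, float(cvs.mean()), se, len(cvs)))
    return out


def cv_table(results: list[CVResult]) -> pd.DataFrame:
    """Tidy table of CV results: period, w, mean_cv, se_cv, n_windows."""
    return pd.DataFrame(
        [
            {"period": r.period, "w": r.window, "mean_cv": r.mean_cv,
             "se_cv": r.se_cv, "n_windows": r.n_windows}
            for r in results
        ]
    )
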