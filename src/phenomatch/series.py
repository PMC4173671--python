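"""Core containers for within-year time series and phenology estimates.

A :class:`DailySeries` holds one year of a seasonal signal (water
temperature, spawner catches, zooplankton counts) indexed by day of year.
Observed days are 1-based; binned series (weekly trap catches) label each
bin by its centre day, which may be half-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DailySeries:
    """One year of a seasonal signal indexed by day of year.

    Parameters
    ----------
    year : int
        Calendar year of the observations.
    days : array-like
        Strictly increasing days of year in ``[1, 366]``.  For binned
        count series each day labels the centre of a bin of width
        ``bin_width``.
    values : array-like
        Measurements (counts or degrees Celsius); same length as ``days``.
    bin_width : float
        Width in days of the interval each observation aggregates.
        1 for daily point measurements, 7 for weekly trap catches.
    """

    year: int
    days: np.ndarray
    values: np.ndarray
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.values.ndim != 1:
            raise ValueError("days and values must be one-dimensional")
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if len(self.days) and not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if len(self.days) and (self.days[0] < 0.5 or self.days[-1] > 366.5):
            raise ValueError("days must lie within the year")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1 day")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def value_on(self, day: float) -> float:
        """Value at an observed day (exact match required)."""
        idx = np.nonzero(self.days == day)[0]
        if len(idx) == 0:
            raise KeyError(f"day {day} not observed in year {self.year}")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class PhenologyEstimate:
    """Gaussian fit of a seasonal event.

    ``mu`` is the estimated peak day (real-valued), ``sigma`` the spread in
    days.  The event duration is defined as four standard deviations
    (roughly the central 95% of the curve).
    """

    year: int
    mu: float
    sigma: float
    n_obs: int
    resid_scale: float = float("nan")
    method: str = "grouped-likelihood"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def duration(self) -> float:
        """Event duration: 4 sigma, the span of ~95% of the activity."""
        return 4.0 * self.sigma


@dataclass(frozen=True)
class HatchPhenology:
    """Larval hatching phenology propagated from a spawning fit.

    ``peak`` is the day of year on which eggs spawned at the spawning
    peak hatch; ``duration`` spans hatching of eggs spawned two standard
    deviations before and after the peak.
    """

    year: int
    peak: float
    duration: float
    spawn_peak: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("hatch duration must be positive")
        if np.isfinite(self.spawn_peak) and self.peak < self.spawn_peak:
            raise ValueError("hatching cannot precede spawning")


@dataclass(frozen=True)
class MismatchIndex:
    """Signed predator-prey timing offset for one year.

    ``pm`` is the zooplankton peak day minus the larval hatching peak
    day: positive when larvae hatch before the prey peak.
    """

    year: int
    pm: float
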