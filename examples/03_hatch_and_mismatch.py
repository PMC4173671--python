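"""Propagate spawning through egg development and compute the mismatch.

Eggs hatch when the cumulative temperature excess over 4.9 degC reaches
97 degree-days; the mismatch index PM is the zooplankton peak day minus
the larval hatching peak day.
"""

import numpy as np

from phenomatch import (
    DailySeries,
    PhenologyEstimate,
    days_to_hatch,
    hatch_phenology,
    mismatch_index,
)

days = np.arange(1, 366, dtype=float)
temps = DailySeries(2000, days, np.full(365, 12.0))
print(f"days to hatch at a constant 12 degC: {days_to_hatch(temps, 130)}")

spawn = PhenologyEstimate(year=2000, mu=130.0, sigma=5.0, n_obs=9)
hatch = hatch_phenology(spawn, temps)
print(f"hatching peak day: {hatch.peak:.0f}  duration: {hatch.duration:.0f} days")

zoop = PhenologyEstimate(year=2000, mu=169.0, sigma=9.0, n_obs=20)
pm = mismatch_index(hatch, zoop)
print(f"mismatch index PM: {pm.pm:+.0f} days")

# PM = +25: larvae hatch 25 days before the zooplankton peak, the kind of
# offset seen when prey phenology lags the predator by three to four weeks.
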