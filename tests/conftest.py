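import numpy as np
import pandas as pd
import pytest

from phenomatch import DailySeries, TruthParams, sample_predictors, gen_recruitment


@pytest.fixture
def constant_temps():
    """A full-year temperature record at a constant 12 degC."""
    def make(value: float = 12.0, year: int = 2000, ndays: int = 365) -> DailySeries:
        days = np.arange(1, ndays + 1, dtype=float)
        return DailySeries(year, days, np.full(ndays, value))

    return make


@pytest.fixture
def recruitment_records():
    """One synthetic year-record frame drawn from the reference coefficients."""
    def make(n_years: int = 300, seed: int = 7, sigma: float = 0.3) -> pd.DataFrame:
        truth = TruthParams.windermere(sigma=sigma)
        pred = sample_predictors(n_years, seed)
        r = gen_recruitment(pred, truth, seed + 100_000)
        return pred.assign(R=r)

    return make
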