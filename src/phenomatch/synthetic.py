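"""Synthetic lake-system data with the statistical structure the analysis assumes.

The generators emulate the Windermere perch--zooplankton study system:
a seasonal water-temperature cycle with a linear warming trend, Gaussian
spawning and zooplankton abundance curves, a two-regime abundance series
around an age--size truncation event, and log-linear recruitment driven by
phenological mismatch, spawning duration and density dependence.

Every generator takes an explicit integer seed; there is no global random
state.  Identical seeds give identical output.
"""

from __future__ import annotations

from calendar import isleap
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import DailySeries

__all__ = [
    "TemperatureConfig",
    "SpawnConfig",
    "TruthParams",
    "PredictorConfig",
    "AbundanceRegime",
    "gen_temperature",
    "gen_spawner_catches",
    "gen_zooplankton",
    "gen_recruitment",
    "gen_abundance",
    "sample_predictors",
    "LakeConfig",
    "simulate_dataset",
]


@dataclass(frozen=True)
class TemperatureConfig:
    """Seasonal surface-temperature model: mean + warming trend + cosine cycle.

    ``peak_day`` is the day of year at which the seasonal term is maximal;
    daily noise is i.i.d. Gaussian.
    """

    annual_mean: float = 10.0
    amplitude: float = 7.0
    peak_day: float = 210.0
    trend: float = 0.02  # degC per year
    noise_sd: float = 0.6
    start_year: int = 1946
    end_year: int = 2012

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.end_year < self.start_year:
            raise ValueError("empty year range")


@dataclass(frozen=True)
class SpawnConfig:
    """Gaussian-in-time spawning season binned into weekly trap hauls."""

    mu: float = 135.0
    sigma: float = 7.0
    n_fish: int = 2000
    bin_width: int = 7
    season_start: float | None = None  # left edge of the first bin

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_fish < 0:
            raise ValueError("n_fish must be non-negative")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1 day")


@dataclass(frozen=True)
class TruthParams:
    """Generative coefficients of the log-linear recruitment model.

    log R = b0 + b1^D * LS + b2 * PM + b3^D * PM^2 + b4 * S^2
            + b5 * CA + b6 * WT + eps,   eps ~ N(0, sigma^2)

    with all continuous predictors centred before powers are formed and
    D the low/high density-dependence dummy split at the median number of
    age-3+ fish.  Units: LS and PM in days, S and CA in individuals, WT in
    degC; the response is the natural log of the recruit count.
    """

    b0: float
    b1_low: float
    b1_high: float
    b2: float
    b3_low: float
    b3_high: float
    b4: float
    b5: float
    b6: float
    sigma: float = 0.3

    def __post_init__(self) -> None:
        vals = (self.b0, self.b1_low, self.b1_high, self.b2, self.b3_low,
                self.b3_high, self.b4, self.b5, self.b6, self.sigma)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all coefficients must be finite")
        if self.sigma < 0:
            raise ValueError("noise sd must be non-negative")

    @classmethod
    def windermere(cls, sigma: float = 0.3) -> "TruthParams":
        """Headline recruitment coefficients estimated for Windermere perch."""
        return cls(
            b0=11.4828,
            b1_low=0.8295,
            b1_high=0.1209,
            b2=0.0607,
            b3_low=-0.0033,
            b3_high=-0.0009,
            b4=2.2e-11,
            b5=-2.9e-5,
            b6=-0.1637,
            sigma=sigma,
        )


@dataclass(frozen=True)
class PredictorConfig:
    """Sampling distributions for the yearly recruitment predictors.

    Defaults span both historical mismatch regimes (three-to-four-week
    offsets as well as near-synchrony) while keeping the design matrix
    well conditioned: PM uniform on [-5, 30] days, LS ~ N(14, 3^2) days,
    S lognormal(ln 30000, 0.4^2), CA lognormal(ln 20000, 0.5^2),
    WT ~ N(4, 1^2) degC.
    """

    pm_range: tuple[float, float] = (-5.0, 30.0)
    ls_mean: float = 14.0
    ls_sd: float = 3.0
    s_log_mean: float = float(np.log(30000.0))
    s_log_sd: float = 0.4
    ca_log_mean: float = float(np.log(20000.0))
    ca_log_sd: float = 0.5
    wt_mean: float = 4.0
    wt_sd: float = 1.0


@dataclass(frozen=True)
class AbundanceRegime:
    """Two-regime lognormal abundance: a truncation event splits the series.

    Years before ``boundary_year`` use the pre-period mean and log-scale
    s.d.; the boundary year itself and later years use the post-period
    values.
    """

    boundary_year: int
    pre_mean: float = 50000.0
    post_mean: float = 30000.0
    pre_log_sd: float = 0.25
    post_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.pre_log_sd < 0 or self.post_log_sd < 0:
            raise ValueError("log-scale sd must be non-negative")
        if self.pre_mean <= 0 or self.post_mean <= 0:
            raise ValueError("period means must be positive")


def gen_temperature(cfg: TemperatureConfig, seed: int) -> list[DailySeries]:
    """Daily water temperature for every year in the configured range.

    Each day's value is annual mean + trend * (year - start) + a cosine
    seasonal term peaking on ``cfg.peak_day`` + Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for year in range(cfg.start_year, cfg.end_year + 1):
        ndays = 366 if isleap(year) else 365
        days = np.arange(1, ndays + 1, dtype=float)
        seasonal = cfg.amplitude * np.cos(2 * np.pi * (days - cfg.peak_day) / ndays)
        level = cfg.annual_mean + cfg.trend * (year - cfg.start_year)
        noise = rng.normal(0.0, cfg.noise_sd, ndays) if cfg.noise_sd > 0 else 0.0
        out.append(DailySeries(year, days, level + seasonal + noise))
    return out


def _bin_edges(cfg: SpawnConfig) -> np.ndarray:
    """Half-open weekly bin edges covering mu +/- 5 sigma."""
    w = cfg.bin_width
    if cfg.season_start is not None:
        start = cfg.season_start
    else:
        start = np.floor(cfg.mu - 5.0 * cfg.sigma - w / 2.0)
    span = cfg.mu + 5.0 * cfg.sigma - start
    nbins = max(int(np.ceil(span / w)), 1)
    return start + w * np.arange(nbins + 1, dtype=float)


def gen_spawner_catches(cfg: SpawnConfig, seed: int, year: int = 2000) -> DailySeries:
    """Weekly spawner catches: N fish multinomially assigned to bins.

    Bin probabilities are Gaussian(mu, sigma) masses over half-open
    intervals ``[edge, edge + width)``; the returned series labels each
    bin by its centre day.  Counts sum exactly to ``cfg.n_fish``.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    edges = _bin_edges(cfg)
    cdf = norm.cdf(edges, loc=cfg.mu, scale=cfg.sigma)
    mass = np.diff(cdf)
    if mass.sum() <= 0:
        raise ValueError("spawning curve has no mass over the season bins")
    probs = mass / mass.sum()
    counts = rng.multinomial(cfg.n_fish, probs)
    centres = edges[:-1] + cfg.bin_width / 2.0
    return DailySeries(year, centres, counts.astype(float), bin_width=cfg.bin_width)


def gen_zooplankton(
    peak: float,
    sigma: float,
    amplitude: float,
    noise_sd: float,
    seed: int,
    year: int = 2000,
    interval: int = 7,
    half_width_sigmas: float = 5.0,
) -> DailySeries:
    """Zooplankton counts along a Gaussian seasonal curve with sampling noise.

    Samples every ``interval`` days symmetrically around the peak; noise is
    multiplicative lognormal (mean-one), so zero-noise output is the exact
    Gaussian curve and counts stay non-negative.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    k = int(np.ceil(half_width_sigmas * sigma / interval))
    days = np.round(peak) + interval * np.arange(-k, k + 1, dtype=float)
    days = days[(days >= 1) & (days <= 365)]
    curve = amplitude * np.exp(-((days - peak) ** 2) / (2.0 * sigma**2))
    if noise_sd > 0:
        curve = curve * np.exp(rng.normal(0.0, noise_sd, len(days)) - noise_sd**2 / 2.0)
    return DailySeries(year, days, curve, bin_width=1.0)


_RECRUIT_FIELDS = ("PM", "LS", "S", "CA", "WT")


def gen_recruitment(
    predictors: pd.DataFrame, truth: TruthParams, seed: int
) -> pd.Series:
    """Recruit counts from the log-linear mismatch/density-dependence model.

    ``predictors`` must contain columns PM, LS, S, CA, WT indexed by spawn
    year.  Continuous predictors are centred in-sample before powers are
    formed; the dummy is low where CA is at or below the sample median.
    Returns exp(linear predictor + Gaussian noise) per year.
    """
    for name in _RECRUIT_FIELDS:
        if name not in predictors.columns:
            raise KeyError(f"missing predictor column: {name}")
        bad = predictors.index[predictors[name].isna()]
        if len(bad):
            raise ValueError(f"missing {name} for year {bad[0]}")
    rng = np.random.default_rng(seed)
    pm = predictors["PM"].to_numpy(float)
    ls = predictors["LS"].to_numpy(float)
    s = predictors["S"].to_numpy(float)
    ca = predictors["CA"].to_numpy(float)
    wt = predictors["WT"].to_numpy(float)

    pm_c = pm - pm.mean()
    ls_c = ls - ls.mean()
    s_c = s - s.mean()
    ca_c = ca - ca.mean()
    wt_c = wt - wt.mean()
    low = ca <= np.median(ca)

    b1 = np.where(low, truth.b1_low, truth.b1_high)
    b3 = np.where(low, truth.b3_low, truth.b3_high)
    log_r = (
        truth.b0
        + b1 * ls_c
        + truth.b2 * pm_c
        + b3 * pm_c**2
        + truth.b4 * s_c**2
        + truth.b5 * ca_c
        + truth.b6 * wt_c
    )
    if truth.sigma > 0:
        log_r = log_r + rng.normal(0.0, truth.sigma, len(log_r))
    return pd.Series(np.exp(log_r), index=predictors.index, name="R")


def gen_abundance(
    regime: AbundanceRegime, n_years: int, seed: int, start_year: int = 1960
) -> pd.Series:
    """Yearly lognormal abundance with a variance/mean shift at the boundary."""
    if n_years < 2:
        raise ValueError("need at least two years")
    end_year = start_year + n_years - 1
    if not (start_year < regime.boundary_year <= end_year):
        raise ValueError("boundary year must fall inside the simulated range")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    post = years >= regime.boundary_year
    mean = np.where(post, regime.post_mean, regime.pre_mean)
    sd = np.where(post, regime.post_log_sd, regime.pre_log_sd)
    vals = mean * np.exp(rng.normal(0.0, 1.0, n_years) * sd)
    return pd.Series(vals, index=pd.Index(years, name="year"), name="abundance")


def sample_predictors(
    n_years: int,
    seed: int,
    cfg: PredictorConfig | None = None,
    start_year: int = 1969,
) -> pd.DataFrame:
    """Draw yearly recruitment predictors from their stand-in distributions."""
    cfg = cfg or PredictorConfig()
    rng = np.random.default_rng(seed)
    years = pd.Index(np.arange(start_year, start_year + n_years), name="year")
    return pd.DataFrame(
        {
            "PM": rng.uniform(*cfg.pm_range, n_years),
            "LS": rng.normal(cfg.ls_mean, cfg.ls_sd, n_years),
            "S": rng.lognormal(cfg.s_log_mean, cfg.s_log_sd, n_years),
            "CA": rng.lognormal(cfg.ca_log_mean, cfg.ca_log_sd, n_years),
            "WT": rng.normal(cfg.wt_mean, cfg.wt_sd, n_years),
        },
        index=years,
    )


@dataclass(frozen=True)
class LakeConfig:
    """Full-system scenario: temperature, spawning, prey phenology, recruitment.

    Spawning and zooplankton peaks advance linearly over years, so the
    mismatch index drifts the way a warming lake drives it; recruitment is
    generated from the phenology actually simulated, closing the loop for
    end-to-end pipeline runs.
    """

    temperature: TemperatureConfig = field(default_factory=TemperatureConfig)
    truth: TruthParams = field(default_factory=TruthParams.windermere)
    predictors: PredictorConfig = field(default_factory=PredictorConfig)
    spawn_mu0: float = 145.0
    spawn_mu_trend: float = -0.2  # days per year (advancing spawning)
    spawn_sigma: float = 6.0
    n_fish: int = 2000
    zoop_peak0: float = 175.0
    zoop_peak_trend: float = -0.45  # prey advances faster than the predator
    zoop_sigma: float = 9.0
    zoop_amplitude: float = 500.0
    zoop_noise_sd: float = 0.15
    mean_size_mm: float = 180.0
    disease_year: int = 1976


def simulate_dataset(cfg: LakeConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Generate a coherent multi-table dataset for the whole pipeline.

    Returns ``temperature``, ``catches`` and ``zooplankton`` long tables
    (year, doy, value) plus a ``yearly`` table of covariates and recruit
    counts.  Recruitment is generated from the simulated true phenology
    (mismatch and hatch duration), not from the downstream estimates, so
    estimator error stays visible to the analysis.
    """
    from .hatchmatch import DegreeDayParams, days_to_hatch

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    temps = gen_temperature(cfg.temperature, seeds[0])
    years = [t.year for t in temps]
    rng = np.random.default_rng(seeds[1])

    catch_rows, zoop_rows, temp_rows = [], [], []
    true_pm, true_ls = {}, {}
    dd = DegreeDayParams()
    for i, (year, tser) in enumerate(zip(years, temps)):
        mu = cfg.spawn_mu0 + cfg.spawn_mu_trend * i
        catches = gen_spawner_catches(
            SpawnConfig(mu=mu, sigma=cfg.spawn_sigma, n_fish=cfg.n_fish),
            seeds[2] + i,
            year=year,
        )
        zpeak = cfg.zoop_peak0 + cfg.zoop_peak_trend * i
        zoop = gen_zooplankton(
            zpeak, cfg.zoop_sigma, cfg.zoop_amplitude, cfg.zoop_noise_sd,
            seeds[3] + i, year=year,
        )
        temp_rows.append(pd.DataFrame({"year": year, "doy": tser.days, "temp_c": tser.values}))
        catch_rows.append(pd.DataFrame({"year": year, "doy": catches.days, "count": catches.values}))
        zoop_rows.append(pd.DataFrame({"year": year, "doy": zoop.days, "count": zoop.values}))

        peak_hatch = round(mu) + days_to_hatch(tser, round(mu), dd)
        lo = round(mu - 2 * cfg.spawn_sigma)
        hi = round(mu + 2 * cfg.spawn_sigma)
        true_ls[year] = (hi + days_to_hatch(tser, hi, dd)) - (lo + days_to_hatch(tser, lo, dd))
        true_pm[year] = zpeak - peak_hatch

    pred = sample_predictors(len(years), seeds[4], cfg.predictors, start_year=years[0])
    pred["PM"] = [true_pm[y] for y in years]
    pred["LS"] = [float(true_ls[y]) for y in years]
    recruits = gen_recruitment(pred, cfg.truth, seeds[5])

    yearly = pd.DataFrame(
        {
            "year": years,
            "spawners": pred["S"].to_numpy(),
            "mean_size_mm": cfg.mean_size_mm + rng.normal(0, 8.0, len(years)),
            "age3plus": pred["CA"].to_numpy(),
            "winter_temp_c": pred["WT"].to_numpy(),
            "disease": [int(y >= cfg.disease_year) for y in years],
            "recruits": recruits.to_numpy(),
        }
    )
    return {
        "temperature": pd.concat(temp_rows, ignore_index=True),
        "catches": pd.concat(catch_rows, ignore_index=True),
        "zooplankton": pd.concat(zoop_rows, ignore_index=True),
        "yearly": yearly,
    }
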