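"""Synthetic weather truth, seasonal forecast ensembles, and sparse observations.

This module emulates the data a seasonal DOC-forecasting chain consumes, so the
whole pipeline is testable offline:

* a daily "truth" weather record per sub-catchment (the role a reanalysis such
  as ERA5 plays): Mediterranean bimodal precipitation seasonality with autumn
  and spring peaks, a dry summer, AR(1)-persistent temperature anomalies, and a
  colder upstream sub-catchment (C1) where snow occurs;
* forecast ensembles (the role of a seasonal prediction system such as SEAS5):
  members whose correlation with truth decays with lead time under a
  controllable signal weight lambda, and whose marginal distributions carry
  controllable additive (temperature) or multiplicative (precipitation) biases;
* sparse monthly grab-sample observations with multiplicative lognormal noise.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import calendars as cal

C1 = "C1"
C2 = "C2"
SUBCATCHMENTS = (C1, C2)

TEMPERATURE = "temperature"
PRECIPITATION = "precipitation"

N_LEADS = 7


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ForcingSeries:
    """Daily temperature (°C) and precipitation (mm d⁻¹) for one sub-catchment."""

    start_year: int
    temperature: np.ndarray
    precipitation: np.ndarray
    subcatchment_id: str
    calendar: str = cal.NOLEAP
    start_doy: int = 0  # 0-based day-of-year of the first sample

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        cal.validate_calendar(self.calendar)
        if self.temperature.shape != self.precipitation.shape:
            raise ValueError("temperature and precipitation must have equal length")
        if np.any(self.precipitation < 0):
            raise ValueError("precipitation must be non-negative")

    def __len__(self) -> int:
        return self.temperature.shape[-1]  # leading axes, if any, are batch dims

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of each day."""
        return cal.month_of_indices(len(self), self.start_doy)

    @property
    def years(self) -> np.ndarray:
        return cal.year_of_indices(len(self), self.start_year, self.start_doy)

    def index_of(self, year: int, month: int = 1, day: int = 1) -> int:
        idx = cal.day_index(self.start_year, year, month, day) - self.start_doy
        if not 0 <= idx <= len(self):
            raise IndexError(f"date {year}-{month:02d}-{day:02d} outside series coverage")
        return idx

    def window(self, year: int, month: int, n_days: int) -> "ForcingSeries":
        """Sub-series of n_days starting on the first of (year, month)."""
        i0 = self.index_of(year, month)
        if i0 + n_days > len(self):
            raise ValueError(
                f"series too short: need {n_days} days from {year}-{month:02d}, "
                f"have {len(self) - i0}"
            )
        return ForcingSeries(
            start_year=year if self.calendar == cal.NOLEAP else self.start_year,
            temperature=self.temperature[..., i0 : i0 + n_days],
            precipitation=self.precipitation[..., i0 : i0 + n_days],
            subcatchment_id=self.subcatchment_id,
            calendar=self.calendar,
            start_doy=cal.doy_of(month, 1),
        )

    def variable(self, name: str) -> np.ndarray:
        if name == TEMPERATURE:
            return self.temperature
        if name == PRECIPITATION:
            return self.precipitation
        raise KeyError(name)


@dataclass
class EnsembleForecast:
    """Daily member trajectories of one variable from one initialization date."""

    variable: str
    init_year: int
    init_month: int
    members: np.ndarray  # shape (n_members, horizon_days)
    subcatchment_id: str

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if self.variable not in (TEMPERATURE, PRECIPITATION):
            raise ValueError(f"unknown variable {self.variable!r}")
        if not 1 <= self.init_month <= 12:
            raise ValueError(f"init_month out of range: {self.init_month}")
        if self.members.shape[0] < 1:
            raise ValueError("ensemble must have at least one member")
        if self.variable == PRECIPITATION and np.any(self.members < 0):
            raise ValueError("precipitation members must be non-negative")

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    @property
    def horizon_days(self) -> int:
        return self.members.shape[1]

    @property
    def months(self) -> np.ndarray:
        """Calendar month of each horizon day (noleap)."""
        return cal.month_of_indices(self.horizon_days, cal.doy_of(self.init_month, 1))

    @property
    def leads(self) -> np.ndarray:
        """Lead month (1-based; lead 1 = initialization month) of each horizon day."""
        doys = cal.doy_of(self.init_month, 1) + np.arange(self.horizon_days)
        month_idx = cal.MONTH_OF_DOY[doys % cal.DAYS_PER_YEAR] - 1
        return (month_idx - (self.init_month - 1)) % 12 + 1


@dataclass
class SkillStructure:
    """Controls how ensemble skill and bias vary with lead month.

    lambda_by_lead weights the truth anomaly in each member (1 = perfect
    correlation with truth, 0 = pure noise); bias_by_lead is additive in °C for
    temperature and multiplicative for precipitation; noise_sd is the standard
    deviation of the independent temperature noise term (°C).
    """

    lambda_by_lead: np.ndarray = field(
        default_factory=lambda: np.array([0.8, 0.55, 0.35, 0.2, 0.1, 0.05, 0.0])
    )
    #: None = unbiased (0 additive for temperature, 1 multiplicative for precipitation)
    bias_by_lead: np.ndarray | None = None
    noise_sd: float = 1.5

    def __post_init__(self) -> None:
        self.lambda_by_lead = np.asarray(self.lambda_by_lead, dtype=float)
        if self.bias_by_lead is not None:
            self.bias_by_lead = np.asarray(self.bias_by_lead, dtype=float)
            if self.bias_by_lead.shape != (N_LEADS,):
                raise ValueError(f"lead vectors must have length {N_LEADS}")
        if self.lambda_by_lead.shape != (N_LEADS,):
            raise ValueError(f"lead vectors must have length {N_LEADS}")
        if np.any((self.lambda_by_lead < 0) | (self.lambda_by_lead > 1)):
            raise ValueError("lambda values must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @staticmethod
    def perfect() -> "SkillStructure":
        return SkillStructure(lambda_by_lead=np.ones(N_LEADS))

    @staticmethod
    def no_skill() -> "SkillStructure":
        return SkillStructure(lambda_by_lead=np.zeros(N_LEADS))

    def with_additive_bias(self, bias: float) -> "SkillStructure":
        return replace(self, bias_by_lead=np.full(N_LEADS, float(bias)))


@dataclass
class ObservationSeries:
    """Sparse timestamped measurements (streamflow m³ s⁻¹ or DOC mg L⁻¹)."""

    day_indices: np.ndarray  # indices into the daily simulation the samples came from
    dates: list[str]
    values: np.ndarray
    variable: str

    def __post_init__(self) -> None:
        self.day_indices = np.asarray(self.day_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.day_indices) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("observed values must be non-negative or missing-flagged")


@dataclass
class ClimateConfig:
    """Parameters of the synthetic weather generator.

    Defaults describe a Mediterranean mid-latitude catchment: warm dry summers,
    wet autumns and springs, and a colder, wetter upstream sub-catchment whose
    winter temperatures support a seasonal snowpack.
    """

    temp_mean: float = 13.0  # °C annual mean at the downstream sub-catchment
    temp_amplitude: float = 8.5  # °C semi-amplitude of the annual cycle
    temp_peak_doy: int = 199  # late July maximum
    temp_ar1: float = 0.7  # day-to-day anomaly persistence
    temp_noise_sd: float = 1.4  # °C innovation noise
    c1_temp_offset: float = -5.0  # elevation lapse: C1 colder than C2
    # monthly wet-day probability, Jan..Dec (autumn/spring peaks, dry summer)
    wet_prob: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.30, 0.28, 0.33, 0.42, 0.40, 0.25, 0.12, 0.16, 0.36, 0.46, 0.40, 0.32]
        )
    )
    # mean wet-day precipitation, mm, Jan..Dec
    wet_mean: np.ndarray = field(
        default_factory=lambda: np.array(
            [6.0, 6.0, 7.0, 9.0, 9.0, 8.0, 5.0, 7.0, 12.0, 14.0, 10.0, 7.0]
        )
    )
    gamma_shape: float = 0.7  # wet-day intensity shape (skewed, heavy-ish tail)
    c1_precip_factor: float = 1.3  # orographic enhancement upstream
    calendar: str = cal.NOLEAP

    def __post_init__(self) -> None:
        self.wet_prob = np.asarray(self.wet_prob, dtype=float)
        self.wet_mean = np.asarray(self.wet_mean, dtype=float)
        if self.wet_prob.shape != (12,) or self.wet_mean.shape != (12,):
            raise ValueError("wet_prob and wet_mean must have 12 monthly values")
        if np.any((self.wet_prob < 0) | (self.wet_prob > 1)):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if np.any(self.wet_mean < 0) or self.gamma_shape <= 0:
            raise ValueError("precipitation intensity parameters must be positive")
        cal.validate_calendar(self.calendar)


# ---------------------------------------------------------------------------
# Truth weather
# ---------------------------------------------------------------------------


def generate_truth_weather(
    config: ClimateConfig, n_years: int, seed: int, start_year: int = 1988
) -> dict[str, ForcingSeries]:
    """Generate the daily truth weather record for both sub-catchments.

    Returns {"C1": ForcingSeries, "C2": ForcingSeries} of n_years × 365 days.
    The two sub-catchments share the same wet/dry day sequence and anomaly
    innovations (they are 30 km apart), differing by the elevation temperature
    offset and the orographic precipitation factor.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    if config.calendar != cal.NOLEAP:
        raise ValueError("truth generation supports the noleap365 calendar only")
    rng = np.random.default_rng(seed)
    n_days = n_years * cal.DAYS_PER_YEAR
    doys = np.arange(n_days) % cal.DAYS_PER_YEAR
    months = cal.MONTH_OF_DOY[doys]

    # Temperature: annual cycle + AR(1) anomalies shared across sub-catchments.
    cycle = config.temp_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (doys - config.temp_peak_doy) / cal.DAYS_PER_YEAR
    )
    innov = rng.normal(0.0, config.temp_noise_sd, size=n_days)
    anom = np.empty(n_days)
    prev = 0.0
    rho = config.temp_ar1
    for i in range(n_days):  # AR(1) recursion
        prev = rho * prev + innov[i]
        anom[i] = prev
    temp_c2 = cycle + anom
    temp_c1 = temp_c2 + config.c1_temp_offset

    # Precipitation: monthly wet-day occurrence, gamma intensities.
    wet = rng.random(n_days) < config.wet_prob[months - 1]
    scale = config.wet_mean[months - 1] / config.gamma_shape
    intensity = rng.gamma(config.gamma_shape, scale)
    precip_c2 = np.where(wet, intensity, 0.0)
    precip_c1 = precip_c2 * config.c1_precip_factor

    return {
        C1: ForcingSeries(start_year, temp_c1, precip_c1, C1, config.calendar),
        C2: ForcingSeries(start_year, temp_c2, precip_c2, C2, config.calendar),
    }


# ---------------------------------------------------------------------------
# Climatology helpers (anomaly definition and gamma-space transform)
# ---------------------------------------------------------------------------


def monthly_climatology(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Per-calendar-month mean over the full record, shape (12,)."""
    return np.array([values[months == m].mean() for m in range(1, 13)])


class _EmpiricalTransform:
    """Invertible empirical probability transform for one calendar month.

    Maps precipitation values to Hazen plotting positions and back; ties
    (notably the dry-day zeros) collapse to the mean plotting position of the
    tied block, so transform→inverse is exact on sample values. This is what
    lets a lambda=1 ensemble reproduce truth bitwise while lambda<1 members
    remain non-negative and month-climatological in distribution.
    """

    def __init__(self, sample: np.ndarray):
        s = np.sort(np.asarray(sample, dtype=float))
        n = len(s)
        if n == 0:
            raise ValueError("empty climatology sample")
        p = (np.arange(n) + 0.5) / n
        uniq, inverse = np.unique(s, return_inverse=True)
        p_mean = np.zeros(len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        np.add.at(p_mean, inverse, p)
        p_mean /= counts
        self.values = uniq
        self.probs = p_mean

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.values, self.probs)

    def quantile(self, p: np.ndarray) -> np.ndarray:
        return np.interp(p, self.probs, self.values)

    def to_gaussian(self, x: np.ndarray) -> np.ndarray:
        p = np.clip(self.cdf(x), 1e-9, 1 - 1e-9)
        return stats.norm.ppf(p)

    def from_gaussian(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(self.quantile(stats.norm.cdf(z)), 0.0)


# ---------------------------------------------------------------------------
# Forecast ensembles
# ---------------------------------------------------------------------------


def generate_ensemble(
    truth: ForcingSeries,
    variable: str,
    init_year: int,
    init_month: int,
    n_members: int,
    skill: SkillStructure,
    seed: int,
    horizon_days: int = cal.PREDICTION_HORIZON_DAYS,
) -> EnsembleForecast:
    """Generate one forecast ensemble with lead-dependent skill and bias.

    Temperature members: monthly-climatology + lambda(lead)·truth anomaly +
    sqrt(1−lambda²)·N(0, noise_sd) + additive bias. Precipitation members are
    built in a transformed Gaussian space per calendar month and mapped back
    through the month's empirical quantiles (so members stay ≥ 0 and keep the
    dry-day mass), then scaled by the multiplicative bias.
    """
    if n_members < 1:
        raise ValueError("n_members must be at least 1")
    window = truth.window(init_year, init_month, horizon_days)  # raises if too short
    rng = np.random.default_rng(seed)

    months_h = window.months
    doys = cal.doy_of(init_month, 1) + np.arange(horizon_days)
    lead_of_day = ((cal.MONTH_OF_DOY[doys % cal.DAYS_PER_YEAR] - 1) - (init_month - 1)) % 12 + 1
    # a 215-day horizon can touch the first days of an 8th calendar month;
    # those days inherit the lead-7 skill parameters
    lead_of_day = np.minimum(lead_of_day, N_LEADS)
    lam = skill.lambda_by_lead[lead_of_day - 1]
    if skill.bias_by_lead is None:
        neutral = 0.0 if variable == TEMPERATURE else 1.0
        bias = np.full(horizon_days, neutral)
    else:
        bias = skill.bias_by_lead[lead_of_day - 1]
    months_all = truth.months

    if variable == TEMPERATURE:
        clim = monthly_climatology(truth.temperature, months_all)
        truth_anom = window.temperature - clim[months_h - 1]
        noise = rng.normal(0.0, skill.noise_sd, size=(n_members, horizon_days))
        anom = lam * truth_anom + np.sqrt(1.0 - lam**2) * noise
        members = clim[months_h - 1] + anom + bias
        if np.all(lam == 1.0) and np.all(bias == 0.0):
            members = np.tile(window.temperature, (n_members, 1))  # exact perfect-skill limit
    elif variable == PRECIPITATION:
        if np.any(bias <= 0):
            raise ValueError("multiplicative precipitation biases must be positive")
        transforms = {m: _EmpiricalTransform(truth.precipitation[months_all == m]) for m in range(1, 13)}
        z_truth = np.empty(horizon_days)
        for m in np.unique(months_h):
            sel = months_h == m
            z_truth[sel] = transforms[m].to_gaussian(window.precipitation[sel])
        noise = rng.normal(0.0, 1.0, size=(n_members, horizon_days))
        z = lam * z_truth + np.sqrt(1.0 - lam**2) * noise
        members = np.empty_like(z)
        for m in np.unique(months_h):
            sel = months_h == m
            members[:, sel] = transforms[m].from_gaussian(z[:, sel])
        if np.all(lam == 1.0):
            members = np.tile(window.precipitation, (n_members, 1))  # exact inversion limit
        members = members * bias
    else:
        raise KeyError(variable)

    return EnsembleForecast(variable, init_year, init_month, members, truth.subcatchment_id)


@dataclass
class HindcastArchive:
    """Collection of ensembles over (variable × sub-catchment × year × init month)."""

    forecasts: dict[tuple[str, str, int, int], EnsembleForecast]
    years: list[int]
    init_months: list[int]
    n_members: int
    variables: tuple[str, ...] = (TEMPERATURE, PRECIPITATION)
    subcatchments: tuple[str, ...] = SUBCATCHMENTS

    def get(self, variable: str, subcatchment: str, year: int, month: int) -> EnsembleForecast:
        return self.forecasts[(variable, subcatchment, year, month)]

    def member_series_count(self, variable: str, subcatchment: str) -> int:
        """Total member trajectories stored for one variable and sub-catchment."""
        return sum(
            fc.n_members
            for (v, s, _, _), fc in self.forecasts.items()
            if v == variable and s == subcatchment
        )

    def map(self, fn) -> "HindcastArchive":
        """New archive with fn applied to every EnsembleForecast."""
        return replace(self, forecasts={k: fn(v) for k, v in self.forecasts.items()})


def build_hindcast_archive(
    truth: dict[str, ForcingSeries],
    years: range | list[int],
    init_months: list[int],
    n_members: int,
    skill: dict[str, SkillStructure] | SkillStructure,
    seed: int,
    variables: tuple[str, ...] = (TEMPERATURE, PRECIPITATION),
    subcatchments: tuple[str, ...] | None = None,
) -> HindcastArchive:
    """One EnsembleForecast per (year × init month × variable × sub-catchment).

    Deterministic under seed: each cell draws from an independent child seed so
    archives are reproducible regardless of iteration order.
    """
    years = list(years)
    init_months = list(init_months)
    if not years:
        raise ValueError("years must be non-empty")
    if not init_months:
        raise ValueError("init_months must be non-empty")
    if any(not 1 <= m <= 12 for m in init_months):
        raise ValueError("init_months must lie in 1..12")
    if subcatchments is None:
        subcatchments = tuple(truth.keys())
    if isinstance(skill, SkillStructure):
        skill = {v: skill for v in variables}

    root = np.random.default_rng(seed)
    forecasts: dict[tuple[str, str, int, int], EnsembleForecast] = {}
    for sc in subcatchments:
        for variable in variables:
            for year in years:
                for month in init_months:
                    child = int(root.integers(0, 2**31 - 1))
                    forecasts[(variable, sc, year, month)] = generate_ensemble(
                        truth[sc], variable, year, month, n_members, skill[variable], child
                    )
    return HindcastArchive(forecasts, years, init_months, n_members, variables, subcatchments)


# ---------------------------------------------------------------------------
# Sparse observations
# ---------------------------------------------------------------------------


def sample_doc_observations(
    sim: np.ndarray,
    cadence: int,
    noise_cv: float,
    seed: int,
    start_year: int = 0,
    start_doy: int = 0,
    variable: str = "doc",
) -> ObservationSeries:
    """Grab samples every `cadence` days with multiplicative lognormal noise.

    Sampling starts on day 0 of the series, so a 365-day series at cadence 30
    yields 13 samples (days 0, 30, ..., 360). The lognormal multiplier has mean
    1 and coefficient of variation noise_cv; noise_cv = 0 reproduces the
    simulated values exactly. Missing (NaN) simulated days are skipped.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.size == 0:
        raise ValueError("empty simulation series")
    if cadence < 1:
        raise ValueError("cadence must be at least 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    idx = np.arange(0, sim.size, cadence)
    values = sim[idx]
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        mult = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=idx.size))
        values = values * mult
    keep = np.isfinite(values)
    idx, values = idx[keep], values[keep]
    dates = [
        f"{y:04d}-{m:02d}-{d:02d}"
        for y, m, d in (cal.date_of_index(start_year, start_doy + int(i)) for i in idx)
    ]
    return ObservationSeries(idx, dates, values, variable)
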