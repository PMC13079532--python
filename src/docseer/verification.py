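"""Ensemble CRPS, climatology references, CRPSS skill grids, and skill classes.

The continuous ranked probability score (CRPS) of an m-member ensemble
{x₁..x_m} against a verifying observation y uses the standard energy (NRG)
estimator,

    CRPS = (1/m) Σᵢ |xᵢ − y| − (1/(2m²)) ΣᵢΣⱼ |xᵢ − xⱼ|,

which equals the integral ∫ (F(x) − 1{x ≥ y})² dx of the empirical CDF F.
An independent piecewise-integration oracle of that integral is provided for
cross-checking. A "fair" (unbiased ensemble-size-adjusted) variant is
available as an option.

Skill is summarized as CRPSS = 1 − CRPS_forecast / CRPS_climatology, where the
climatology reference is the ensemble of that calendar month's values across
the reference years, by default excluding the verifying year (leave-one-out),
and CRPS is averaged over verification years before the ratio is taken. A
CRPSS of 1 is a perfect forecast, 0 matches climatology, negative is worse
than climatology. Grids span 12 initialization months × 7 lead months and are
computed identically for temperature, precipitation, streamflow and DOC.

Traffic-light classes: high (CRPSS > 0.6), acceptable (0.2 ≤ CRPSS ≤ 0.6),
none (CRPSS < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

N_LEADS = 7


# ---------------------------------------------------------------------------
# CRPS
# ---------------------------------------------------------------------------


def crps_ensemble(members: np.ndarray, obs: float, fair: bool = False) -> float:
    """CRPS of one ensemble against one observation (NRG estimator).

    With fair=True the member-spread term uses the unbiased 1/(2m(m−1))
    normalization instead of 1/(2m²).
    """
    x = np.asarray(members, dtype=float).ravel()
    m = x.size
    if m == 0:
        raise ValueError("empty ensemble")
    if not (np.all(np.isfinite(x)) and np.isfinite(obs)):
        raise ValueError("non-finite ensemble member or observation")
    term_obs = np.mean(np.abs(x - obs))
    if m == 1:
        return float(term_obs)
    spread = np.abs(x[:, None] - x[None, :]).sum()
    denom = 2 * m * (m - 1) if fair else 2 * m * m
    return float(term_obs - spread / denom)


def crps_integral_oracle(members: np.ndarray, obs: float) -> float:
    """Exact piecewise integral of (F(x) − 1{x ≥ y})² for the empirical CDF F.

    Independent of the energy-form estimator: integrates the squared
    difference between the empirical step CDF and the observation step
    function segment by segment over the sorted breakpoints.
    """
    x = np.sort(np.asarray(members, dtype=float).ravel())
    m = x.size
    if m == 0:
        raise ValueError("empty ensemble")
    points = np.unique(np.concatenate([x, [float(obs)]]))
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        f = np.searchsorted(x, a, side="right") / m  # F on (a, b)
        h = 1.0 if a >= obs else 0.0  # heaviside on (a, b): 1 once x ≥ obs
        total += (f - h) ** 2 * (b - a)
    return float(total)


# ---------------------------------------------------------------------------
# Climatology reference
# ---------------------------------------------------------------------------


def climatology_ensemble(
    monthly: dict[tuple[int, int], float],
    calendar_month: int,
    ref_years: list[int] | range,
    exclude_year: int | None = None,
) -> np.ndarray:
    """Climatological reference ensemble for one calendar month.

    Members are the monthly-mean values of that calendar month across the
    reference years, optionally excluding the verifying year (leave-one-out).
    """
    ref_years = list(ref_years)
    if len(ref_years) < 3:
        raise ValueError("reference period must span at least 3 years")
    vals = [
        monthly[(y, calendar_month)]
        for y in ref_years
        if y != exclude_year and (y, calendar_month) in monthly
    ]
    if not vals:
        raise ValueError(
            f"no climatology members for month {calendar_month} in {ref_years}"
        )
    return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# Skill grid
# ---------------------------------------------------------------------------


class SkillClass(str, Enum):
    HIGH = "high"
    ACCEPTABLE = "acceptable"
    NONE = "none"


def classify_skill(crpss: float) -> SkillClass:
    """Traffic-light class with printed boundary semantics (0.6 and 0.2 → acceptable)."""
    if not np.isfinite(crpss):
        raise ValueError("CRPSS must be finite")
    if crpss > 0.6:
        return SkillClass.HIGH
    if crpss >= 0.2:
        return SkillClass.ACCEPTABLE
    return SkillClass.NONE


@dataclass
class SkillGrid:
    """CRPSS per (initialization month × lead), with per-cell sample counts."""

    variable: str
    crpss: np.ndarray  # (12, N_LEADS); NaN where flagged missing
    n_samples: np.ndarray  # (12, N_LEADS) verification instances per cell
    init_months: list[int]

    def cell(self, init_month: int, lead: int) -> float:
        return float(self.crpss[init_month - 1, lead - 1])

    def classes(self) -> np.ndarray:
        out = np.empty(self.crpss.shape, dtype=object)
        for idx, v in np.ndenumerate(self.crpss):
            out[idx] = classify_skill(v).value if np.isfinite(v) else None
        return out

    def to_records(self) -> list[dict]:
        recs = []
        for im in self.init_months:
            for lead in range(1, N_LEADS + 1):
                v = self.cell(im, lead)
                recs.append({
                    "variable": self.variable,
                    "init_month": im,
                    "lead": lead,
                    "crpss": v if np.isfinite(v) else None,
                    "n": int(self.n_samples[im - 1, lead - 1]),
                    "class": classify_skill(v).value if np.isfinite(v) else None,
                })
        return recs


def crpss_cell(
    forecasts: dict[int, np.ndarray],
    observed: dict[int, float],
    climatology: dict[int, np.ndarray],
) -> tuple[float, int]:
    """CRPSS for one (init month, lead) cell.

    forecasts / climatology map verification year → ensemble of monthly means;
    observed maps year → verifying monthly mean. The skill score is the ratio
    of CRPS summed (equivalently averaged) over years — the skill of the
    system, not the mean of per-year ratios. Returns (crpss, n_years); NaN
    with n < 2 or degenerate (zero) climatology CRPS flags the cell missing.
    """
    years = sorted(set(forecasts) & set(observed) & set(climatology))
    if len(years) < 2:
        return float("nan"), len(years)
    crps_fc = np.mean([crps_ensemble(forecasts[y], observed[y]) for y in years])
    crps_cl = np.mean([crps_ensemble(climatology[y], observed[y]) for y in years])
    if crps_cl == 0:
        return float("nan"), len(years)
    return float(1.0 - crps_fc / crps_cl), len(years)


def crpss_grid(
    forecast_monthly: dict[tuple[int, int, int], np.ndarray],
    obs_monthly: dict[tuple[int, int], float],
    ref_years: list[int] | range,
    variable: str = "",
    init_months: list[int] | None = None,
    loo_climatology: bool = True,
    n_leads: int = N_LEADS,
) -> SkillGrid:
    """CRPSS over initialization months × leads.

    forecast_monthly maps (init_month, year, lead) → ensemble of monthly means
    for the lead's calendar month; obs_monthly maps (year, calendar_month) →
    verifying pseudo-observed monthly mean; the climatology reference ensemble
    is built from obs_monthly over ref_years, excluding the verifying year
    when loo_climatology is set.
    """
    ref_years = list(ref_years)
    if init_months is None:
        init_months = sorted({k[0] for k in forecast_monthly})
    grid = np.full((12, n_leads), np.nan)
    counts = np.zeros((12, n_leads), dtype=int)
    for im in init_months:
        for lead in range(1, n_leads + 1):
            month = (im - 1 + lead - 1) % 12 + 1
            fcs, obs, clim = {}, {}, {}
            for (i, year, ld), ens in forecast_monthly.items():
                if i != im or ld != lead:
                    continue
                # the lead's calendar month may fall in the following year
                v_year = year + ((im - 1 + lead - 1) // 12)
                if (v_year, month) not in obs_monthly:
                    continue
                fcs[year] = ens
                obs[year] = obs_monthly[(v_year, month)]
                clim[year] = climatology_ensemble(
                    obs_monthly, month, ref_years,
                    exclude_year=v_year if loo_climatology else None,
                )
            val, n = crpss_cell(fcs, obs, clim)
            grid[im - 1, lead - 1] = val
            counts[im - 1, lead - 1] = n
    return SkillGrid(variable=variable, crpss=grid, n_samples=counts, init_months=init_months)
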