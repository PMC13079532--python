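"""Goodness-of-fit metrics and Monte-Carlo parameter search.

Metrics follow their standard hydrological definitions:

    NSE    = 1 − Σ(o−s)² / Σ(o−ō)²
    logNSE = NSE computed on ln(x + ε), ε = 1% of the mean observed value
    KGE    = 1 − sqrt((r−1)² + (α−1)² + (β−1)²),  α = σ_s/σ_o,  β = μ_s/μ_o
    R²     = squared Pearson correlation

All metrics are evaluated at monthly aggregation for the seasonal use case
(daily also supported). The Monte-Carlo search perturbs named parameters
uniformly within ±25% of their base values and screens out candidates whose
carbon pools drift more than 1%/yr over the final simulated year, mirroring
a stability requirement for slow-pool models.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import calendars as cal
from .catchment import CatchmentConfig, run_simulation, compile_config, SOC_O, SOC_M, DOC
from .synthetic import ForcingSeries, ObservationSeries


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_monthly(
    values: np.ndarray,
    start_year: int,
    start_doy: int = 0,
    require_complete: bool = True,
) -> dict[tuple[int, int], float]:
    """Arithmetic mean per (year, month) instance of a daily noleap series.

    Months that are not fully covered by the series, or that contain any
    missing (NaN) day, are dropped when require_complete is set. Returns an
    ordered {(year, month): mean} mapping.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input series")
    n = values.size
    years = cal.year_of_indices(n, start_year, start_doy)
    months = cal.month_of_indices(n, start_doy)
    out: dict[tuple[int, int], float] = {}
    keys = years * 12 + (months - 1)
    for key in np.unique(keys):
        sel = keys == key
        y, m0 = divmod(int(key), 12)
        n_exp = int(cal.MONTH_LENGTHS[m0])
        vals = values[sel]
        if require_complete and (vals.size != n_exp or np.any(~np.isfinite(vals))):
            continue
        out[(y, m0 + 1)] = float(np.nanmean(vals)) if vals.size else np.nan
    return out


def monthly_means_of_samples(obs: ObservationSeries, start_year: int, start_doy: int = 0
                             ) -> dict[tuple[int, int], float]:
    """Mean of grab samples within each (year, month); months with no sample absent."""
    out: dict[tuple[int, int], list[float]] = {}
    for idx, v in zip(obs.day_indices, obs.values):
        y, m, _ = cal.date_of_index(start_year, start_doy + int(idx))
        out.setdefault((y, m), []).append(float(v))
    return {k: float(np.mean(v)) for k, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# GOF metrics
# ---------------------------------------------------------------------------


@dataclass
class GOFReport:
    r2: float
    nse: float
    lognse: float
    kge: float
    aggregation: str
    n_pairs: int


def _pairwise(obs, sim):
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("obs and sim must have equal length")
    keep = np.isfinite(obs) & np.isfinite(sim)
    return obs[keep], sim[keep]


def nse(obs, sim) -> float:
    obs, sim = _pairwise(obs, sim)
    if obs.size < 2:
        raise ValueError("need at least 2 paired values")
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise ValueError("zero observed variance: NSE undefined")
    return float(1.0 - np.sum((obs - sim) ** 2) / denom)


def kge(obs, sim) -> float:
    obs, sim = _pairwise(obs, sim)
    if obs.size < 2:
        raise ValueError("need at least 2 paired values")
    so, ss = obs.std(ddof=0), sim.std(ddof=0)
    mo, ms = obs.mean(), sim.mean()
    if so == 0 or mo == 0:
        return float("nan")  # undefined component: flagged missing, not fabricated
    r = np.corrcoef(obs, sim)[0, 1] if ss > 0 else np.nan
    if not np.isfinite(r):
        return float("nan")
    return float(1.0 - np.sqrt((r - 1) ** 2 + (ss / so - 1) ** 2 + (ms / mo - 1) ** 2))


def gof_metrics(obs, sim, aggregation: str = "monthly") -> GOFReport:
    """All four metrics on paired observation/simulation values."""
    o, s = _pairwise(obs, sim)
    if o.size < 2:
        raise ValueError("need at least 2 paired values after missing-data deletion")
    eps = 0.01 * float(np.mean(o)) if np.mean(o) > 0 else 1e-6
    if o.std(ddof=0) > 0 and s.std(ddof=0) > 0:
        r2 = float(np.corrcoef(o, s)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return GOFReport(
        r2=r2,
        nse=nse(o, s),
        lognse=nse(np.log(o + eps), np.log(s + eps)),
        kge=kge(o, s),
        aggregation=aggregation,
        n_pairs=int(o.size),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------


@dataclass
class MCCandidate:
    params: dict[str, float]
    objective: float
    nse_q: float
    nse_doc: float
    drift: float
    unstable: bool


@dataclass
class MCResult:
    best: dict[str, float]
    objective: float
    trace: list[MCCandidate] = field(default_factory=list)
    all_unstable: bool = False


# parameter paths supported by the ±25% sweep: (object, attribute)
def _set_param(config: CatchmentConfig, name: str, value: float) -> None:
    """Set `name` = "<hydro|carbon>.<attr>" on every land-cover unit of every reach."""
    group, attr = name.split(".")
    for reach in config.reaches:
        for unit in reach.land_cover.values():
            target = unit.hydro if group == "hydro" else unit.carbon
            if not hasattr(target, attr):
                raise KeyError(f"unknown parameter {name!r}")
            setattr(target, attr, value)


def _get_param(config: CatchmentConfig, name: str) -> float:
    group, attr = name.split(".")
    unit = next(iter(config.reaches[0].land_cover.values()))
    return getattr(unit.hydro if group == "hydro" else unit.carbon, attr)


def _scale_param(config: CatchmentConfig, name: str, factor: float) -> None:
    group, attr = name.split(".")
    for reach in config.reaches:
        for unit in reach.land_cover.values():
            target = unit.hydro if group == "hydro" else unit.carbon
            setattr(target, attr, getattr(target, attr) * factor)


def monte_carlo_calibrate(
    config: CatchmentConfig,
    forcing: dict[str, ForcingSeries],
    obs_q: ObservationSeries,
    obs_doc: ObservationSeries,
    param_names: list[str],
    n_iter: int,
    seed: int,
    obs_reach: str = "C2",
    weight_q: float = 0.5,
    spread: float = 0.25,
    drift_limit: float = 0.01,
) -> MCResult:
    """Uniform ±`spread` Monte-Carlo search around the base parameter values.

    Objective = weight_q·NSE(monthly Q) + (1−weight_q)·NSE(monthly DOC), where
    monthly DOC pairs grab-sample means against monthly means of the daily
    simulation. Candidates whose carbon pools drift more than `drift_limit`
    per year over the final simulated year are flagged unstable and excluded
    from selection; if every candidate is unstable the base configuration is
    returned with all_unstable set.

    Parameter factors are scaled multiplicatively on every land-cover unit, so
    the relative structure between land covers is preserved.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    base = {name: _get_param(config, name) for name in param_names}
    ref = next(iter(forcing.values()))
    start_year, start_doy = ref.start_year, ref.start_doy

    trace: list[MCCandidate] = []
    for _ in range(n_iter):
        factors = {name: float(rng.uniform(1 - spread, 1 + spread)) for name in param_names}
        cand_cfg = copy.deepcopy(config)
        for name, f in factors.items():
            _scale_param(cand_cfg, name, f)
        trace.append(_evaluate_candidate(
            cand_cfg, forcing, obs_q, obs_doc, obs_reach, weight_q, drift_limit,
            {n: base[n] * f for n, f in factors.items()}, start_year, start_doy,
        ))

    stable = [c for c in trace if not c.unstable]
    if not stable:
        return MCResult(best=dict(base), objective=float("nan"), trace=trace, all_unstable=True)
    best = max(stable, key=lambda c: c.objective)
    return MCResult(best=dict(best.params), objective=best.objective, trace=trace)


def _evaluate_candidate(cfg, forcing, obs_q, obs_doc, obs_reach, weight_q, drift_limit,
                        params, start_year, start_doy) -> MCCandidate:
    out = run_simulation(cfg, forcing)
    ri = out.reach(obs_reach)
    n_days = out.n_days
    n_years = max(n_days / cal.DAYS_PER_YEAR, 1e-9)

    pools = out.final_state.pools[..., [SOC_O, SOC_M, DOC]]
    # drift over final year: compare to pools one year before the end
    if n_days > cal.DAYS_PER_YEAR:
        trimmed = {rid: _trim_forcing(forcing[rid], n_days - cal.DAYS_PER_YEAR)
                   for rid in out.reach_ids}
        mid = run_simulation(cfg, trimmed).final_state.pools[..., [SOC_O, SOC_M, DOC]]
        drift = float(np.max(np.abs(pools - mid) / np.maximum(np.abs(mid), 1e-9)))
    else:
        init = compile_config(cfg).init_pools[..., [SOC_O, SOC_M, DOC]]
        drift = float(np.max(np.abs(pools - init) / np.maximum(np.abs(init), 1e-9))) / n_years

    sim_q_m = aggregate_monthly(out.streamflow[ri], start_year, start_doy)
    sim_doc_m = aggregate_monthly(out.doc[ri], start_year, start_doy, require_complete=False)
    obs_q_m = monthly_means_of_samples(obs_q, start_year, start_doy)
    obs_doc_m = monthly_means_of_samples(obs_doc, start_year, start_doy)

    nse_q = _nse_on_common(obs_q_m, sim_q_m)
    nse_doc = _nse_on_common(obs_doc_m, sim_doc_m)
    objective = weight_q * nse_q + (1 - weight_q) * nse_doc
    return MCCandidate(params=params, objective=objective, nse_q=nse_q, nse_doc=nse_doc,
                       drift=drift, unstable=drift > drift_limit)


def _trim_forcing(f: ForcingSeries, n: int) -> ForcingSeries:
    return ForcingSeries(f.start_year, f.temperature[:n], f.precipitation[:n],
                         f.subcatchment_id, f.calendar, f.start_doy)


def _nse_on_common(obs_m: dict, sim_m: dict) -> float:
    keys = sorted(set(obs_m) & set(sim_m))
    if len(keys) < 2:
        return float("nan")
    return nse([obs_m[k] for k in keys], [sim_m[k] for k in keys])
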