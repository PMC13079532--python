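"""Minimal semi-distributed daily rainfall–runoff and soil-carbon/DOC simulator.

This is deliberately *not* a re-implementation of any published catchment
model: it is a compact stand-in with the same I/O contract as a coupled
rainfall-runoff → in-soil carbon chain (daily temperature and precipitation in;
hydrologically effective rainfall HER, soil moisture deficit SMD, streamflow
and DOC concentration out) and the two properties a seasonal DOC-forecasting
workflow exploits:

* streamflow is mediated by HER/SMD from a bucket water balance with a snow
  store, so flow responds quickly to weather;
* DOC is exported from slow soil organic carbon pools, so concentrations carry
  multi-month to multi-year memory of antecedent conditions.

Structure: two reaches (C1 upstream, colder, snow-influenced; C2 downstream,
more urbanized, with a continuous WWTP point source), each split into
land-cover units (urban, agriculture, broad-leaved forest, coniferous forest,
small/no vegetation) that run independent vertical columns and aggregate by
area share. Numerics: explicit Euler at a daily step with proportional flux
capping so no store or pool ever goes negative; water and carbon balances
close to round-off by construction.

All state arrays carry the unit axis last, so an arbitrary leading batch axis
(e.g. ensemble members) broadcasts through the whole simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import calendars as cal
from .synthetic import ForcingSeries

LAND_COVERS = ("urban", "agriculture", "broadleaf_forest", "coniferous_forest", "sparse")

# state vector layout (last axis of the packed pools array)
SNOW, SOIL, QUICK, SLOW, SOC_O, SOC_M, DOC = range(7)
N_STATE = 7
STATE_NAMES = ("snowpack", "soil_water", "quick_store", "slow_store",
               "soc_organic", "soc_mineral", "doc_pool")

MM_KM2_TO_M3S = 1000.0 / 86400.0  # mm d⁻¹ over km² → m³ s⁻¹
EPS_EXPORT = 0.1  # mm; regularizes the export fraction HER/(S+eps) in dry soil


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class HydroParams:
    """Bucket-hydrology parameters for one land-cover unit.

    t_snow: rain/snow split temperature (°C); ddf: degree-day snowmelt factor
    (mm °C⁻¹ d⁻¹); a_pet: PET per degree above 0 °C (mm °C⁻¹ d⁻¹); c_soil:
    soil water capacity (mm); beta_q: fraction of HER routed to the quick
    reservoir; tau_q/tau_s: quick/slow linear-reservoir time constants (d).
    """

    t_snow: float = 0.0
    ddf: float = 3.0
    a_pet: float = 0.22
    c_soil: float = 150.0
    beta_q: float = 0.5
    tau_q: float = 3.0
    tau_s: float = 70.0

    def validate(self) -> None:
        if self.ddf < 0 or self.a_pet < 0:
            raise ValueError("ddf and a_pet must be non-negative")
        if self.c_soil <= 0:
            raise ValueError("c_soil must be positive")
        if not 0.0 <= self.beta_q <= 1.0:
            raise ValueError("beta_q must lie in [0, 1]")
        if self.tau_q < 1.0 or self.tau_s < 1.0:
            raise ValueError("reservoir time constants must be ≥ 1 day")


@dataclass
class CarbonParams:
    """Soil-carbon parameters for one land-cover unit.

    k_p: first-order DOC production rate from the organic pool (d⁻¹); q10 and
    t_ref set the temperature sensitivity; k_sorb: sorption of dissolved carbon
    to the mineral pool (d⁻¹); k_min: in-soil mineralization loss (d⁻¹);
    i_litter: litter carbon entering the dissolved-producing organic pool
    (g C m⁻² d⁻¹); c_gw: DOC concentration of slow (groundwater) flow (mg L⁻¹).
    """

    k_p: float = 2.0e-4
    q10: float = 2.0
    t_ref: float = 10.0
    k_sorb: float = 0.005
    k_min: float = 0.010
    i_litter: float = 0.02
    c_gw: float = 1.5

    def validate(self) -> None:
        if min(self.k_p, self.k_sorb, self.k_min, self.i_litter, self.c_gw) < 0:
            raise ValueError("carbon rate parameters must be non-negative")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")


@dataclass
class LandCoverUnit:
    share: float
    hydro: HydroParams
    carbon: CarbonParams
    init_soc_organic: float = 100.0  # g C m⁻²
    init_soc_mineral: float = 200.0
    init_doc_pool: float = 0.8


@dataclass
class PointSource:
    concentration: float  # mg L⁻¹
    flow: float  # m³ s⁻¹

    def validate(self) -> None:
        if self.flow < 0 or self.concentration < 0:
            raise ValueError("point-source flow and concentration must be non-negative")


@dataclass
class Reach:
    reach_id: str
    area_km2: float
    land_cover: dict[str, LandCoverUnit]
    point_sources: list[PointSource] = field(default_factory=list)
    upstream: str | None = None  # reach discharging into this one
    k_instream: float = 0.05  # fraction of upstream DOC load lost in transit

    def validate(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"reach {self.reach_id}: area must be positive")
        total = sum(u.share for u in self.land_cover.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reach {self.reach_id}: land-cover shares sum to {total}, not 1")
        if any(u.share < 0 or u.share > 1 for u in self.land_cover.values()):
            raise ValueError(f"reach {self.reach_id}: shares must lie in [0, 1]")
        if not 0.0 <= self.k_instream <= 1.0:
            raise ValueError("k_instream must lie in [0, 1]")
        for u in self.land_cover.values():
            u.hydro.validate()
            u.carbon.validate()
        for ps in self.point_sources:
            ps.validate()


@dataclass
class CatchmentConfig:
    """Ordered upstream→downstream reach configuration."""

    reaches: list[Reach]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.reach_id for r in self.reaches]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reach ids")
        seen: set[str] = set()
        for r in self.reaches:
            r.validate()
            if r.upstream is not None and r.upstream not in seen:
                raise ValueError(
                    f"reach {r.reach_id}: upstream {r.upstream!r} must precede it "
                    "(reaches are in topological order)"
                )
            seen.add(r.reach_id)

    @property
    def reach_ids(self) -> list[str]:
        return [r.reach_id for r in self.reaches]


def demo_catchment() -> CatchmentConfig:
    """Two-reach Mediterranean demonstration catchment.

    C1: mountainous, forested, snow-influenced headwater. C2: downstream,
    more agricultural/urban, receives C1 plus a continuous treated-wastewater
    point source of 12 mg L⁻¹ DOC at 0.13 m³ s⁻¹.
    """

    def unit(share, c_soil, beta_q, i_litter, soc_o, c_gw):
        return LandCoverUnit(
            share=share,
            hydro=HydroParams(c_soil=c_soil, beta_q=beta_q),
            carbon=CarbonParams(i_litter=i_litter, c_gw=c_gw),
            init_soc_organic=soc_o,
            init_soc_mineral=2 * soc_o,
        )

    c1 = Reach(
        reach_id="C1",
        area_km2=780.0,
        land_cover={
            "urban": unit(0.02, 50.0, 0.9, 0.002, 15.0, 3.0),
            "agriculture": unit(0.08, 120.0, 0.6, 0.010, 70.0, 2.5),
            "broadleaf_forest": unit(0.25, 160.0, 0.45, 0.022, 150.0, 1.5),
            "coniferous_forest": unit(0.45, 180.0, 0.40, 0.026, 180.0, 1.5),
            "sparse": unit(0.20, 80.0, 0.70, 0.004, 30.0, 1.0),
        },
    )
    c2 = Reach(
        reach_id="C2",
        area_km2=900.0,
        land_cover={
            "urban": unit(0.10, 50.0, 0.9, 0.002, 15.0, 3.0),
            "agriculture": unit(0.40, 120.0, 0.6, 0.010, 70.0, 2.5),
            "broadleaf_forest": unit(0.25, 160.0, 0.45, 0.022, 150.0, 1.5),
            "coniferous_forest": unit(0.20, 180.0, 0.40, 0.026, 180.0, 1.5),
            "sparse": unit(0.05, 80.0, 0.70, 0.004, 30.0, 1.0),
        },
        point_sources=[PointSource(concentration=12.0, flow=0.13)],
        upstream="C1",
    )
    return CatchmentConfig(reaches=[c1, c2])


# ---------------------------------------------------------------------------
# Compiled parameter arrays (one entry per land-cover unit across all reaches)
# ---------------------------------------------------------------------------


@dataclass
class _Compiled:
    reach_ids: list[str]
    unit_reach: np.ndarray  # (n_units,) reach index of each unit
    share: np.ndarray
    area_km2: np.ndarray  # per reach
    upstream: list[int | None]  # per reach
    k_instream: np.ndarray  # per reach
    ps_flow: np.ndarray  # per reach, total point-source flow m³ s⁻¹
    ps_load: np.ndarray  # per reach, total point-source DOC load g s⁻¹
    # per-unit hydro
    t_snow: np.ndarray
    ddf: np.ndarray
    a_pet: np.ndarray
    c_soil: np.ndarray
    beta_q: np.ndarray
    tau_q: np.ndarray
    tau_s: np.ndarray
    # per-unit carbon
    k_p: np.ndarray
    q10: np.ndarray
    t_ref: np.ndarray
    k_sorb: np.ndarray
    k_min: np.ndarray
    i_litter: np.ndarray
    c_gw: np.ndarray
    init_pools: np.ndarray  # (n_units, N_STATE)

    @property
    def n_units(self) -> int:
        return len(self.share)

    @property
    def n_reaches(self) -> int:
        return len(self.reach_ids)


def compile_config(config: CatchmentConfig) -> _Compiled:
    config.validate()
    rows: list[tuple[int, LandCoverUnit]] = []
    for ri, reach in enumerate(config.reaches):
        for lc in LAND_COVERS:
            if lc in reach.land_cover:
                rows.append((ri, reach.land_cover[lc]))
        for lc in reach.land_cover:
            if lc not in LAND_COVERS:
                raise ValueError(f"unknown land cover {lc!r}")
    arr = lambda f: np.array([f(u) for _, u in rows], dtype=float)
    init = np.zeros((len(rows), N_STATE))
    for i, (_, u) in enumerate(rows):
        init[i, SOIL] = 0.7 * u.hydro.c_soil
        init[i, QUICK] = 1.0
        init[i, SLOW] = 20.0
        init[i, SOC_O] = u.init_soc_organic
        init[i, SOC_M] = u.init_soc_mineral
        init[i, DOC] = u.init_doc_pool
    id_index = {r.reach_id: i for i, r in enumerate(config.reaches)}
    return _Compiled(
        reach_ids=config.reach_ids,
        unit_reach=np.array([ri for ri, _ in rows], dtype=int),
        share=arr(lambda u: u.share),
        area_km2=np.array([r.area_km2 for r in config.reaches]),
        upstream=[None if r.upstream is None else id_index[r.upstream] for r in config.reaches],
        k_instream=np.array([r.k_instream for r in config.reaches]),
        ps_flow=np.array([sum(p.flow for p in r.point_sources) for r in config.reaches]),
        ps_load=np.array(
            [sum(p.concentration * p.flow for p in r.point_sources) for r in config.reaches]
        ),
        t_snow=arr(lambda u: u.hydro.t_snow),
        ddf=arr(lambda u: u.hydro.ddf),
        a_pet=arr(lambda u: u.hydro.a_pet),
        c_soil=arr(lambda u: u.hydro.c_soil),
        beta_q=arr(lambda u: u.hydro.beta_q),
        tau_q=arr(lambda u: u.hydro.tau_q),
        tau_s=arr(lambda u: u.hydro.tau_s),
        k_p=arr(lambda u: u.carbon.k_p),
        q10=arr(lambda u: u.carbon.q10),
        t_ref=arr(lambda u: u.carbon.t_ref),
        k_sorb=arr(lambda u: u.carbon.k_sorb),
        k_min=arr(lambda u: u.carbon.k_min),
        i_litter=arr(lambda u: u.carbon.i_litter),
        c_gw=arr(lambda u: u.carbon.c_gw),
        init_pools=init,
    )


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """Packed state: pools[..., unit, variable] with layout STATE_NAMES.

    Leading axes (if any) are batch dimensions (e.g. ensemble members). `year`,
    `month`, `day` date the state (state valid at the start of that day).
    """

    pools: np.ndarray
    year: int = 0
    month: int = 1
    day: int = 1

    def __post_init__(self) -> None:
        self.pools = np.asarray(self.pools, dtype=float)
        if self.pools.shape[-1] != N_STATE:
            raise ValueError(f"state last axis must have length {N_STATE}")
        if np.any(self.pools < 0):
            raise ValueError("all stores and pools must be non-negative")

    def copy(self) -> "ModelState":
        return ModelState(self.pools.copy(), self.year, self.month, self.day)

    def carbon_total(self) -> np.ndarray:
        return self.pools[..., [SOC_O, SOC_M, DOC]].sum(axis=-1)


def default_state(config: CatchmentConfig, year: int = 0) -> ModelState:
    return ModelState(compile_config(config).init_pools.copy(), year=year)


# ---------------------------------------------------------------------------
# Process steps (array cores; broadcast over any leading batch axes)
# ---------------------------------------------------------------------------


def step_hydrology(pools: np.ndarray, T: np.ndarray, P: np.ndarray, cp: _Compiled):
    """One daily bucket-hydrology step for all land-cover units.

    Precipitation falls as snow below t_snow; melt follows a degree-day law
    capped by the snowpack. PET is temperature-proportional and actual ET
    scales with relative soil moisture (capped by available water). Water
    exceeding the soil capacity becomes hydrologically effective rainfall
    (HER), split between quick and slow linear reservoirs. Returns the updated
    pools array and a dict of per-unit fluxes (all in mm d⁻¹ except SMD in mm).
    """
    T = np.asarray(T, dtype=float)[..., None] if np.ndim(T) < pools.ndim - 1 else np.asarray(T, float)
    P = np.asarray(P, dtype=float)[..., None] if np.ndim(P) < pools.ndim - 1 else np.asarray(P, float)
    out = pools.copy()
    snow, S = pools[..., SNOW], pools[..., SOIL]
    sq, ss = pools[..., QUICK], pools[..., SLOW]

    is_snow = T < cp.t_snow
    snowfall = np.where(is_snow, P, 0.0)
    rain = P - snowfall
    melt = np.minimum(snow, cp.ddf * np.maximum(0.0, T - cp.t_snow))
    pet = cp.a_pet * np.maximum(0.0, T)
    water_in = rain + melt
    aet = np.minimum(pet * S / cp.c_soil, S + water_in)
    her = np.maximum(0.0, S + water_in - aet - cp.c_soil)
    s_new = S + water_in - aet - her  # within [0, c_soil] by construction
    q_quick = (sq + cp.beta_q * her) / cp.tau_q
    q_slow = (ss + (1.0 - cp.beta_q) * her) / cp.tau_s

    out[..., SNOW] = snow + snowfall - melt
    out[..., SOIL] = s_new
    out[..., QUICK] = sq + cp.beta_q * her - q_quick
    out[..., SLOW] = ss + (1.0 - cp.beta_q) * her - q_slow
    fluxes = {
        "rain": rain, "snowfall": snowfall, "snowmelt": melt, "pet": pet, "aet": aet,
        "her": her, "smd": cp.c_soil - s_new, "q_quick": q_quick, "q_slow": q_slow,
    }
    return out, fluxes


def step_carbon(pools: np.ndarray, hydro_fluxes: dict, T: np.ndarray, cp: _Compiled):
    """One daily soil-carbon step for all land-cover units.

    DOC production moves carbon from the organic pool to the dissolved pool at
    a rate scaled by a Q10 temperature factor and relative soil moisture; the
    dissolved pool loses carbon to sorption (→ mineral pool), mineralization
    (out of the system) and hydrological export (out via quickflow, with the
    exported fraction HER/(S+eps) capped at 1). Explicit Euler with
    proportional capping: if demanded outflows exceed a pool, all its outflows
    scale down together, so pools stay non-negative.
    """
    if not (np.all(np.isfinite(np.asarray(T, float)))):
        raise ValueError("non-finite temperature forcing")
    T = np.asarray(T, dtype=float)[..., None] if np.ndim(T) < pools.ndim - 1 else np.asarray(T, float)
    out = pools.copy()
    soc_o, soc_m, d = pools[..., SOC_O], pools[..., SOC_M], pools[..., DOC]
    her = hydro_fluxes["her"]
    S = cp.c_soil - hydro_fluxes["smd"]  # end-of-day soil water

    f_temp = cp.q10 ** ((T - cp.t_ref) / 10.0)
    production = cp.k_p * soc_o * f_temp * (S / cp.c_soil)
    production = np.minimum(production, soc_o)  # cap: cannot exceed source pool

    f_export = np.minimum(1.0, her / (S + EPS_EXPORT))
    sorption = cp.k_sorb * d
    mineralization = cp.k_min * d
    export = d * f_export
    demand = sorption + mineralization + export
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(demand > d, np.where(demand > 0, d / np.maximum(demand, 1e-300), 1.0), 1.0)
    sorption, mineralization, export = sorption * scale, mineralization * scale, export * scale

    # maximum(·, 0) clears the ~1e-16 negatives the capped-outflow arithmetic
    # can leave when a pool is drained exactly
    out[..., SOC_O] = np.maximum(soc_o + cp.i_litter - production, 0.0)
    out[..., SOC_M] = soc_m + sorption
    out[..., DOC] = np.maximum(d + production - sorption - mineralization - export, 0.0)
    fluxes = {
        "production": production, "sorption": sorption,
        "mineralization": mineralization, "export": export,
    }
    return out, fluxes


def route_network(cp: _Compiled, runoff_depth: np.ndarray, terr_load: np.ndarray,
                  gw_load: np.ndarray):
    """Route per-reach local runoff and DOC load downstream.

    runoff_depth: mm d⁻¹ per reach (area-share aggregated); terr_load and
    gw_load: g C s⁻¹ per reach. Q_reach = local + upstream + point sources;
    load_reach = terrestrial + groundwater + upstream·(1−k_instream) + point
    sources; concentration = load/Q (NaN where Q = 0). Arrays carry the reach
    axis last; leading axes broadcast.
    """
    n_r = cp.n_reaches
    q = np.empty_like(runoff_depth)
    load = np.empty_like(runoff_depth)
    for ri in range(n_r):
        q_local = runoff_depth[..., ri] * cp.area_km2[ri] * MM_KM2_TO_M3S + cp.ps_flow[ri]
        l_local = terr_load[..., ri] + gw_load[..., ri] + cp.ps_load[ri]
        up = cp.upstream[ri]
        if up is not None:
            q_local = q_local + q[..., up]
            l_local = l_local + load[..., up] * (1.0 - cp.k_instream[ri])
        q[..., ri] = q_local
        load[..., ri] = l_local
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(q > 0, load / np.where(q > 0, q, 1.0), np.nan)
    return q, load, conc


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationOutput:
    """Daily per-reach outputs plus final state and balance diagnostics.

    Arrays have shape batch + (n_reaches, n_days). DOC concentration is NaN
    (missing-flagged) on days with zero streamflow.
    """

    reach_ids: list[str]
    streamflow: np.ndarray  # m³ s⁻¹
    doc: np.ndarray  # mg L⁻¹
    load: np.ndarray  # g C s⁻¹
    her: np.ndarray  # mm d⁻¹, area-share aggregated
    smd: np.ndarray  # mm, area-share aggregated
    final_state: ModelState
    start_year: int
    start_doy: int = 0
    trajectory: np.ndarray | None = None  # (n_days+1,) + batch + (n_units, N_STATE)
    water_balance: dict | None = None
    carbon_balance: dict | None = None

    @property
    def n_days(self) -> int:
        return self.streamflow.shape[-1]

    def reach(self, reach_id: str) -> int:
        return self.reach_ids.index(reach_id)

    def water_balance_error(self) -> float:
        """Max relative water-balance closure error across units."""
        wb = self.water_balance
        resid = wb["input"] - wb["aet"] - wb["outflow"] - wb["storage_change"]
        denom = max(float(np.max(wb["precip"])), 1e-12)
        return float(np.max(np.abs(resid)) / denom)

    def carbon_balance_error(self) -> float:
        cb = self.carbon_balance
        resid = cb["litter"] - cb["mineralization"] - cb["export"] - cb["pool_change"]
        denom = max(float(np.max(np.abs(cb["litter"]) + cb["initial_pool"])), 1e-12)
        return float(np.max(np.abs(resid)) / denom)


def run_simulation(
    config: CatchmentConfig | _Compiled,
    forcing: dict[str, ForcingSeries] | dict[str, dict[str, np.ndarray]],
    initial: ModelState | None = None,
    record_trajectory: bool = False,
) -> SimulationOutput:
    """Run the coupled daily simulation over aligned per-reach forcing.

    `forcing` maps each reach id to either a ForcingSeries or a dict with
    "temperature"/"precipitation" arrays; member batches are supported by
    passing arrays of shape (m, n_days) together with an initial state of
    shape (m, n_units, N_STATE) (a shared (n_units, N_STATE) state broadcasts).
    """
    cp = config if isinstance(config, _Compiled) else compile_config(config)
    temps, precips, meta = [], [], None
    for rid in cp.reach_ids:
        f = forcing[rid]
        if isinstance(f, ForcingSeries):
            temps.append(f.temperature)
            precips.append(f.precipitation)
            m = (f.start_year, f.start_doy, len(f))
        else:
            temps.append(np.asarray(f["temperature"], dtype=float))
            precips.append(np.asarray(f["precipitation"], dtype=float))
            m = (f.get("start_year", 0), f.get("start_doy", 0), temps[-1].shape[-1])
        if meta is None:
            meta = m
        elif m[2] != meta[2]:
            raise ValueError("forcing series misaligned across reaches")
    start_year, start_doy, n_days = meta
    n_days = int(n_days)

    if initial is None:
        initial = ModelState(cp.init_pools.copy(), year=start_year)
    pools = np.array(initial.pools, dtype=float, copy=True)
    batch = np.broadcast_shapes(pools.shape[:-2], temps[0].shape[:-1])
    pools = np.broadcast_to(pools, batch + pools.shape[-2:]).copy()

    n_r, n_u = cp.n_reaches, cp.n_units
    out_q = np.empty(batch + (n_r, n_days))
    out_conc = np.empty(batch + (n_r, n_days))
    out_load = np.empty(batch + (n_r, n_days))
    out_her = np.empty(batch + (n_r, n_days))
    out_smd = np.empty(batch + (n_r, n_days))
    traj = np.empty((n_days + 1,) + batch + (n_u, N_STATE)) if record_trajectory else None
    if traj is not None:
        traj[0] = pools

    # balance accumulators (per unit)
    acc_in = np.zeros(batch + (n_u,))
    acc_aet = np.zeros(batch + (n_u,))
    acc_out = np.zeros(batch + (n_u,))
    acc_precip = np.zeros(batch + (n_u,))
    acc_litter = np.zeros(batch + (n_u,))
    acc_minr = np.zeros(batch + (n_u,))
    acc_exp = np.zeros(batch + (n_u,))
    water0 = pools[..., [SOIL, QUICK, SLOW]].sum(axis=-1)  # snow balances separately
    carbon0 = pools[..., [SOC_O, SOC_M, DOC]].sum(axis=-1)

    ur = cp.unit_reach
    share = cp.share
    area_u = cp.area_km2[ur]  # km² of the reach each unit belongs to
    # reach aggregation matrix: agg[r, u] = share if unit u in reach r
    agg = np.zeros((n_r, n_u))
    agg[ur, np.arange(n_u)] = share
    # unit export gC m⁻² d⁻¹ → reach load g s⁻¹:  × share × area_km2 × 1e6 / 86400
    exp_factor = share * area_u * 1e6 / 86400.0
    gw_factor = share * area_u * MM_KM2_TO_M3S  # unit slowflow mm/d → m³ s⁻¹
    onehot = _one_hot(ur, n_r)

    for t in range(n_days):
        T_r = np.stack([tv[..., t] for tv in temps], axis=-1)  # batch + (n_r,)
        P_r = np.stack([pv[..., t] for pv in precips], axis=-1)
        T_u = T_r[..., ur]
        P_u = P_r[..., ur]
        pools, hf = step_hydrology(pools, T_u, P_u, cp)
        pools, cf = step_carbon(pools, hf, T_u, cp)

        runoff_u = hf["q_quick"] + hf["q_slow"]
        runoff_depth = runoff_u @ agg.T  # batch + (n_r,)
        terr_load = (cf["export"] * exp_factor) @ onehot
        gw_load = (cp.c_gw * hf["q_slow"] * gw_factor) @ onehot
        q, load, conc = route_network(cp, runoff_depth, terr_load, gw_load)

        out_q[..., t] = q
        out_load[..., t] = load
        out_conc[..., t] = conc
        out_her[..., t] = hf["her"] @ agg.T
        out_smd[..., t] = hf["smd"] @ agg.T

        acc_in += hf["rain"] + hf["snowmelt"]
        acc_aet += hf["aet"]
        acc_out += runoff_u
        acc_precip += hf["rain"] + hf["snowfall"]
        acc_litter += np.broadcast_to(cp.i_litter, acc_litter.shape)
        acc_minr += cf["mineralization"]
        acc_exp += cf["export"]
        if traj is not None:
            traj[t + 1] = pools

    end_year, end_month, end_day = cal.date_of_index(start_year, start_doy + n_days)
    wb = {
        "input": acc_in,
        "aet": acc_aet,
        "outflow": acc_out,
        "storage_change": pools[..., [SOIL, QUICK, SLOW]].sum(axis=-1) - water0,
        "precip": acc_precip,
    }
    cb = {
        "litter": acc_litter,
        "mineralization": acc_minr,
        "export": acc_exp,
        "pool_change": pools[..., [SOC_O, SOC_M, DOC]].sum(axis=-1) - carbon0,
        "initial_pool": carbon0,
    }
    return SimulationOutput(
        reach_ids=list(cp.reach_ids),
        streamflow=out_q,
        doc=out_conc,
        load=out_load,
        her=out_her,
        smd=out_smd,
        final_state=ModelState(pools, end_year, end_month, end_day),
        start_year=start_year,
        start_doy=start_doy,
        trajectory=traj,
        water_balance=wb,
        carbon_balance=cb,
    )


def _one_hot(idx: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((len(idx), n))
    m[np.arange(len(idx)), idx] = 1.0
    return m


# ---------------------------------------------------------------------------
# Spin-up
# ---------------------------------------------------------------------------


def spin_up(
    config: CatchmentConfig,
    forcing_year: dict[str, ForcingSeries],
    n_years: int,
    initial: ModelState | None = None,
) -> tuple[ModelState, float]:
    """Repeat one forcing year n_years times from default initial pools.

    Returns the final state and a drift diagnostic: the maximum relative
    change of any carbon pool over the final repeated year. Small drift means
    the slow pools have converged to a periodic cycle under that climate.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    cp = compile_config(config)
    state = initial.copy() if initial is not None else default_state(config)
    prev_carbon = None
    for _ in range(n_years):
        prev_carbon = state.pools[..., [SOC_O, SOC_M, DOC]].copy()
        out = run_simulation(cp, forcing_year, initial=state)
        state = out.final_state
    now = state.pools[..., [SOC_O, SOC_M, DOC]]
    drift = float(np.max(np.abs(now - prev_carbon) / np.maximum(np.abs(prev_carbon), 1e-9)))
    return state, drift


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------


def config_to_yaml(config: CatchmentConfig, path) -> None:
    doc = {"reaches": []}
    for r in config.reaches:
        doc["reaches"].append({
            "reach_id": r.reach_id,
            "area_km2": r.area_km2,
            "upstream": r.upstream,
            "k_instream": r.k_instream,
            "point_sources": [
                {"concentration": p.concentration, "flow": p.flow} for p in r.point_sources
            ],
            "land_cover": {
                lc: {
                    "share": u.share,
                    "hydro": vars(u.hydro).copy(),
                    "carbon": vars(u.carbon).copy(),
                    "init_soc_organic": u.init_soc_organic,
                    "init_soc_mineral": u.init_soc_mineral,
                    "init_doc_pool": u.init_doc_pool,
                }
                for lc, u in r.land_cover.items()
            },
        })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> CatchmentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    reaches = []
    for rd in doc["reaches"]:
        land = {
            lc: LandCoverUnit(
                share=ud["share"],
                hydro=HydroParams(**ud["hydro"]),
                carbon=CarbonParams(**ud["carbon"]),
                init_soc_organic=ud.get("init_soc_organic", 100.0),
                init_soc_mineral=ud.get("init_soc_mineral", 200.0),
                init_doc_pool=ud.get("init_doc_pool", 0.8),
            )
            for lc, ud in rd["land_cover"].items()
        }
        reaches.append(
            Reach(
                reach_id=rd["reach_id"],
                area_km2=rd["area_km2"],
                land_cover=land,
                point_sources=[PointSource(**p) for p in rd.get("point_sources", [])],
                upstream=rd.get("upstream"),
                k_instream=rd.get("k_instream", 0.05),
            )
        )
    return CatchmentConfig(reaches=reaches)
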