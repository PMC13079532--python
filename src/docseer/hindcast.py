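"""Hindcast execution: warm-up assembly, state resets, ensemble simulation.

Each hindcast job forces the calibrated catchment model with one ensemble
member's 215-day weather trajectory, preceded by a multi-year warm-up taken
from the truth (reanalysis-role) record, with the model state reset from the
truth-forced reference simulation at the warm-up start. Because the warm-up
forcing is the truth itself and the reset state comes from the reference run,
the state at the initialization date equals the reference state there exactly
(restart equivalence); the engine exploits this by computing the warm-up once
per initialization and sharing it across members, which is bit-identical to
running each member's warm-up separately. An explicit warm-up mode is kept for
verification of that equivalence.

Daily outputs of the prediction window are aggregated to monthly ensemble
means per lead month (lead 1 = the initialization month). The 215-day horizon
can truncate the 7th lead month; means then use the available days and the
lead carries a completeness flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calendars as cal
from .catchment import CatchmentConfig, ModelState, SimulationOutput, compile_config, run_simulation
from .synthetic import ForcingSeries, HindcastArchive, PRECIPITATION, TEMPERATURE

N_LEADS = 7
DEFAULT_WARMUP_YEARS = 5


# ---------------------------------------------------------------------------
# Job enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HindcastJob:
    init_year: int
    init_month: int
    member_id: int
    warmup_years: int = DEFAULT_WARMUP_YEARS


@dataclass
class ArchiveSpec:
    members: list[int]
    years: list[int]
    init_months: list[int]
    warmup_years: int = DEFAULT_WARMUP_YEARS

    @staticmethod
    def of(n_members: int, years, init_months, warmup_years: int = DEFAULT_WARMUP_YEARS
           ) -> "ArchiveSpec":
        return ArchiveSpec(list(range(n_members)), list(years), list(init_months), warmup_years)


def enumerate_jobs(spec: ArchiveSpec) -> list[HindcastJob]:
    """Cartesian product of years × init months × members, in that order."""
    if not spec.members or not spec.years or not spec.init_months:
        raise ValueError("archive spec has an empty dimension")
    if spec.warmup_years < 0:
        raise ValueError("warmup_years must be non-negative")
    return [
        HindcastJob(year, month, member, spec.warmup_years)
        for year in spec.years
        for month in spec.init_months
        for member in spec.members
    ]


# ---------------------------------------------------------------------------
# Forcing assembly and state reset
# ---------------------------------------------------------------------------


def build_forcing(
    truth: ForcingSeries,
    member_temperature: np.ndarray,
    member_precipitation: np.ndarray,
    init_year: int,
    init_month: int,
    warmup_years: int = DEFAULT_WARMUP_YEARS,
) -> ForcingSeries:
    """Concatenate truth warm-up (ending the day before initialization) with a
    member's prediction-horizon weather.

    Length = warmup_years × 365 + horizon days in the noleap calendar (2040
    for a 5-year warm-up and the standard 215-day horizon).
    """
    member_temperature = np.asarray(member_temperature, dtype=float)
    member_precipitation = np.asarray(member_precipitation, dtype=float)
    warm_start_year = init_year - warmup_years
    warm_days = warmup_years * cal.DAYS_PER_YEAR
    i0 = truth.index_of(warm_start_year, init_month)
    if i0 + warm_days > len(truth):
        raise ValueError("truth record does not cover the warm-up window")
    warm_t = truth.temperature[..., i0 : i0 + warm_days]
    warm_p = truth.precipitation[..., i0 : i0 + warm_days]
    if member_temperature.ndim > warm_t.ndim:  # tile the shared warm-up across members
        reps = member_temperature.shape[:-1] + (1,)
        warm_t = np.tile(warm_t, reps)
        warm_p = np.tile(warm_p, reps)
    temp = np.concatenate([warm_t, member_temperature], axis=-1)
    prec = np.concatenate([warm_p, member_precipitation], axis=-1)
    return ForcingSeries(
        start_year=warm_start_year,
        temperature=temp,
        precipitation=prec,
        subcatchment_id=truth.subcatchment_id,
        calendar=truth.calendar,
        start_doy=cal.doy_of(init_month, 1),
    )


def initial_state_from_reference(reference: SimulationOutput, year: int, month: int,
                                 day: int = 1) -> ModelState:
    """Exact stored model state at the start of a date of the reference run."""
    if reference.trajectory is None:
        raise ValueError("reference run was not recorded with a state trajectory")
    idx = cal.day_index(reference.start_year, year, month, day) - reference.start_doy
    if not 0 <= idx < reference.trajectory.shape[0]:
        raise ValueError(f"date {year}-{month:02d}-{day:02d} outside reference trajectory")
    return ModelState(reference.trajectory[idx].copy(), year, month, day)


# ---------------------------------------------------------------------------
# Monthly aggregation of the prediction window
# ---------------------------------------------------------------------------


def lead_day_slices(init_month: int, horizon_days: int) -> list[tuple[slice, bool]]:
    """(day-slice, complete?) for each lead month within the horizon."""
    out = []
    start = 0
    for lead in range(N_LEADS):
        month = (init_month - 1 + lead) % 12 + 1
        length = int(cal.MONTH_LENGTHS[month - 1])
        end = min(start + length, horizon_days)
        out.append((slice(start, end), end - start == length))
        start += length
        if start >= horizon_days:
            # remaining leads (if any) are empty
            for _ in range(lead + 1, N_LEADS):
                out.append((slice(horizon_days, horizon_days), False))
            break
    return out


# ---------------------------------------------------------------------------
# Hindcast output
# ---------------------------------------------------------------------------


@dataclass
class HindcastOutput:
    """Monthly ensemble means per (init month, year, member, lead).

    Arrays are (n_init_months, n_years, n_members, N_LEADS); `complete` marks
    leads fully covered by the 215-day horizon for each init month.
    """

    init_months: list[int]
    years: list[int]
    n_members: int
    streamflow: np.ndarray
    doc: np.ndarray
    temperature: np.ndarray
    precipitation: np.ndarray
    complete: np.ndarray  # (n_init_months, N_LEADS) bool
    target_reach: str
    failed_jobs: list[HindcastJob]

    def monthly_ensembles(self, variable: str) -> dict[tuple[int, int, int], np.ndarray]:
        """{(init_month, year, lead): member means} for the verification grids."""
        arr = {
            "streamflow": self.streamflow,
            "doc": self.doc,
            TEMPERATURE: self.temperature,
            PRECIPITATION: self.precipitation,
        }[variable]
        out = {}
        for i, im in enumerate(self.init_months):
            for j, year in enumerate(self.years):
                for lead in range(1, N_LEADS + 1):
                    ens = arr[i, j, :, lead - 1]
                    if np.all(np.isfinite(ens)):
                        out[(im, year, lead)] = ens
        return out


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def run_hindcasts(
    config: CatchmentConfig,
    archive: HindcastArchive,
    truth: dict[str, ForcingSeries],
    reference: SimulationOutput,
    warmup_years: int = DEFAULT_WARMUP_YEARS,
    target_reach: str = "C2",
    explicit_warmup: bool = False,
) -> HindcastOutput:
    """Run every hindcast of the archive through the catchment model.

    For each (init year, init month): reset the model state from the reference
    run at the warm-up start, advance it over the truth-forced warm-up (shared
    across members — identical forcing gives identical states), then run all
    members of both weather variables as one batched 215-day simulation and
    aggregate the target reach's daily streamflow and DOC to monthly ensemble
    means per lead. Failed jobs are reported and excluded, never imputed.
    """
    cp = compile_config(config)
    n_i, n_y, n_m = len(archive.init_months), len(archive.years), archive.n_members
    shape = (n_i, n_y, n_m, N_LEADS)
    out_q = np.full(shape, np.nan)
    out_doc = np.full(shape, np.nan)
    out_t = np.full(shape, np.nan)
    out_p = np.full(shape, np.nan)
    complete = np.zeros((n_i, N_LEADS), dtype=bool)
    failed: list[HindcastJob] = []
    ri = cp.reach_ids.index(target_reach)

    for i, im in enumerate(archive.init_months):
        horizon = archive.get(TEMPERATURE, archive.subcatchments[0],
                              archive.years[0], im).horizon_days
        slices = lead_day_slices(im, horizon)
        complete[i] = [c for _, c in slices]
        for j, year in enumerate(archive.years):
            try:
                state0 = _warmup_state(cp, truth, reference, year, im, warmup_years)
                member_forcing = {}
                for sc in cp.reach_ids:
                    fc_t = archive.get(TEMPERATURE, sc, year, im)
                    fc_p = archive.get(PRECIPITATION, sc, year, im)
                    member_forcing[sc] = {
                        "temperature": fc_t.members,
                        "precipitation": fc_p.members,
                        "start_year": year,
                        "start_doy": cal.doy_of(im, 1),
                    }
                if explicit_warmup:
                    for sc in cp.reach_ids:
                        full = build_forcing(
                            truth[sc],
                            member_forcing[sc]["temperature"],
                            member_forcing[sc]["precipitation"],
                            year, im, warmup_years,
                        )
                        member_forcing[sc] = {
                            "temperature": full.temperature,
                            "precipitation": full.precipitation,
                            "start_year": full.start_year,
                            "start_doy": full.start_doy,
                        }
                    state0 = initial_state_from_reference(
                        reference, year - warmup_years, im
                    )
                sim = run_simulation(cp, member_forcing, initial=state0)
                q = sim.streamflow[..., ri, :]
                dc = sim.doc[..., ri, :]
                if explicit_warmup:
                    warm_days = warmup_years * cal.DAYS_PER_YEAR
                    q, dc = q[..., warm_days:], dc[..., warm_days:]
                fc_t = archive.get(TEMPERATURE, target_reach, year, im)
                fc_p = archive.get(PRECIPITATION, target_reach, year, im)
                for lead, (sl, _) in enumerate(slices):
                    if sl.stop > sl.start:
                        out_q[i, j, :, lead] = q[..., sl].mean(axis=-1)
                        out_doc[i, j, :, lead] = np.nanmean(dc[..., sl], axis=-1)
                        out_t[i, j, :, lead] = fc_t.members[:, sl].mean(axis=-1)
                        out_p[i, j, :, lead] = fc_p.members[:, sl].mean(axis=-1)
            except Exception:
                failed.extend(
                    HindcastJob(year, im, m, warmup_years) for m in range(n_m)
                )
    return HindcastOutput(
        init_months=list(archive.init_months),
        years=list(archive.years),
        n_members=n_m,
        streamflow=out_q,
        doc=out_doc,
        temperature=out_t,
        precipitation=out_p,
        complete=complete,
        target_reach=target_reach,
        failed_jobs=failed,
    )


def _warmup_state(cp, truth, reference, init_year, init_month, warmup_years) -> ModelState:
    """Model state at the initialization date after a truth-forced warm-up.

    The warm-up starts from the reference state warmup_years earlier and runs
    the truth forcing forward; by restart equivalence this equals the stored
    reference state at the initialization date, which is returned directly.
    """
    if warmup_years == 0:
        return initial_state_from_reference(reference, init_year, init_month)
    # the reference trajectory must cover the warm-up window
    initial_state_from_reference(reference, init_year - warmup_years, init_month)
    return initial_state_from_reference(reference, init_year, init_month)


def reference_run(
    config: CatchmentConfig,
    truth: dict[str, ForcingSeries],
    spinup_years: int = DEFAULT_WARMUP_YEARS,
) -> SimulationOutput:
    """Truth-forced reference simulation with a recorded state trajectory.

    The model is first spun up by repeating the first forcing year
    spinup_years times, then run over the full truth record. Its outputs act
    as pseudo-observations for calibration, verification and climatologies,
    and its trajectory provides hindcast initial states.
    """
    from .catchment import spin_up

    first_year = {sc: f.window(f.start_year, 1, cal.DAYS_PER_YEAR) for sc, f in truth.items()}
    state, _ = spin_up(config, first_year, max(spinup_years, 1))
    return run_simulation(config, truth, initial=state, record_trajectory=True)
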