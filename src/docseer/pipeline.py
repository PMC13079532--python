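"""End-to-end orchestration of the seasonal DOC-forecasting chain.

One call wires the whole workflow together on synthetic data: truth weather →
truth-forced reference simulation (pseudo-observations) → hindcast ensemble
archive (optionally bias-corrected with leave-one-year-out EQM) → catchment
hindcast runs → CRPSS skill grids per variable → tercile climatologies and a
monthly forecast report. Both the command-line interface and the acceptance
experiments are thin layers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calendars as cal
from .biascorrect import correct_archive_loo
from .catchment import CatchmentConfig, demo_catchment
from .gof import aggregate_monthly
from .hindcast import HindcastOutput, reference_run, run_hindcasts
from .products import (
    MonthlyReport,
    TercileClimatology,
    assemble_report,
    tercile_climatology,
)
from .synthetic import (
    ClimateConfig,
    ForcingSeries,
    HindcastArchive,
    PRECIPITATION,
    SkillStructure,
    TEMPERATURE,
    build_hindcast_archive,
    generate_truth_weather,
)
from .verification import SkillGrid, crpss_grid

VARIABLES = (TEMPERATURE, PRECIPITATION, "streamflow", "doc")


@dataclass
class PipelineResult:
    truth: dict[str, ForcingSeries]
    reference: object  # SimulationOutput with trajectory
    archive: HindcastArchive
    hindcast: HindcastOutput
    obs_monthly: dict[str, dict[tuple[int, int], float]]
    grids: dict[str, SkillGrid] = field(default_factory=dict)


def ensemble_monthly_means(
    archive: HindcastArchive, variable: str, subcatchment: str = "C2"
) -> dict[tuple[int, int, int], np.ndarray]:
    """{(init_month, year, lead): member monthly means} straight from an archive.

    Pure ensemble statistics of the weather members (no catchment model);
    leads truncated by the 215-day horizon are reported from available days.
    """
    from .hindcast import lead_day_slices

    out: dict[tuple[int, int, int], np.ndarray] = {}
    for (var, sc, year, month), fc in archive.forecasts.items():
        if var != variable or sc != subcatchment:
            continue
        for lead, (sl, _) in enumerate(lead_day_slices(month, fc.horizon_days), start=1):
            if sl.stop > sl.start:
                out[(month, year, lead)] = fc.members[:, sl].mean(axis=1)
    return out


def pseudo_obs_monthly(
    truth: dict[str, ForcingSeries], reference, target_reach: str = "C2"
) -> dict[str, dict[tuple[int, int], float]]:
    """Monthly pseudo-observation means for all four verified variables."""
    t = truth[target_reach]
    ri = reference.reach_ids.index(target_reach)
    return {
        TEMPERATURE: aggregate_monthly(t.temperature, t.start_year, t.start_doy),
        PRECIPITATION: aggregate_monthly(t.precipitation, t.start_year, t.start_doy),
        "streamflow": aggregate_monthly(
            reference.streamflow[ri], reference.start_year, reference.start_doy
        ),
        "doc": aggregate_monthly(
            reference.doc[ri], reference.start_year, reference.start_doy,
            require_complete=False,
        ),
    }


def run_pipeline(
    seed: int,
    truth_years: int = 20,
    start_year: int = 1993,
    hindcast_years: list[int] | range | None = None,
    init_months: list[int] | None = None,
    n_members: int = 10,
    skill: dict[str, SkillStructure] | SkillStructure | None = None,
    config: CatchmentConfig | None = None,
    climate: ClimateConfig | None = None,
    bias_correct: bool = False,
    warmup_years: int = 5,
    target_reach: str = "C2",
    compute_grids: bool = True,
) -> PipelineResult:
    """Run the full chain on synthetic data and return every intermediate.

    Hindcast initialization years default to all truth years that leave room
    for the warm-up before and the 215-day horizon after.
    """
    config = config or demo_catchment()
    climate = climate or ClimateConfig()
    skill = skill if skill is not None else SkillStructure()
    truth = generate_truth_weather(climate, truth_years, seed, start_year)
    if init_months is None:
        init_months = list(range(1, 13))
    if hindcast_years is None:
        first = start_year + warmup_years
        last = start_year + truth_years - 2  # leave the final year for horizons
        hindcast_years = range(first, last + 1)
    hindcast_years = list(hindcast_years)

    reference = reference_run(config, truth)
    archive = build_hindcast_archive(
        truth, hindcast_years, init_months, n_members, skill, seed + 1
    )
    if bias_correct:
        archive = correct_archive_loo(archive, truth)
    hc = run_hindcasts(
        config, archive, truth, reference, warmup_years=warmup_years,
        target_reach=target_reach,
    )
    obs_monthly = pseudo_obs_monthly(truth, reference, target_reach)

    result = PipelineResult(truth, reference, archive, hc, obs_monthly)
    if compute_grids:
        for var in VARIABLES:
            result.grids[var] = crpss_grid(
                hc.monthly_ensembles(var),
                obs_monthly[var],
                ref_years=hindcast_years,
                variable=var,
                init_months=init_months,
            )
    return result


def forecast_report(
    result: PipelineResult,
    init_year: int,
    init_month: int,
    climate_ref_years: list[int] | range | None = None,
    flux_ref_years: list[int] | range | None = None,
) -> MonthlyReport:
    """Monthly report for one initialization present in the hindcast output.

    Tercile climatologies use separate reference windows for the climate
    variables and for streamflow/DOC; both default to the hindcast years
    (a later window for the fluxes can reflect regime shifts such as upstream
    treatment-plant installation).
    """
    hc = result.hindcast
    years = hc.years
    climate_ref_years = list(climate_ref_years or years)
    flux_ref_years = list(flux_ref_years or years)
    climatologies: dict[str, TercileClimatology] = {}
    for var in VARIABLES:
        ref = climate_ref_years if var in (TEMPERATURE, PRECIPITATION) else flux_ref_years
        climatologies[var] = tercile_climatology(result.obs_monthly[var], ref, var)

    if init_month not in hc.init_months or init_year not in years:
        raise ValueError(
            f"initialization {init_year}-{init_month:02d} not in the hindcast set "
            f"(years {years[0]}..{years[-1]}, init months {hc.init_months})"
        )
    i = hc.init_months.index(init_month)
    j = years.index(init_year)
    ensembles = {
        "doc": {ld: hc.doc[i, j, :, ld - 1] for ld in range(1, 8)},
        "temperature": {ld: hc.temperature[i, j, :, ld - 1] for ld in range(1, 8)},
        "precipitation": {ld: hc.precipitation[i, j, :, ld - 1] for ld in range(1, 8)},
        "streamflow": {ld: hc.streamflow[i, j, :, ld - 1] for ld in range(1, 8)},
    }
    return assemble_report(
        init_year, init_month, ensembles, climatologies, result.grids["doc"],
        provenance={
            "target_reach": hc.target_reach,
            "bias_correction": "eqm-loo" if getattr(result.archive, "corrected", False) else "raw",
        },
    )
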