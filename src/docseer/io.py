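"""Reading and writing the pipeline's data products.

Daily series and observations travel as two-column CSV (date, value) or as
NetCDF; ensembles as NetCDF with (member, time) layout and initialization
metadata; skill grids as CSV/JSON. NetCDF files are written through xarray's
scipy backend (NetCDF3), which keeps the on-disk format dependency-light.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import xarray as xr

from . import calendars as cal
from .synthetic import EnsembleForecast, ForcingSeries, ObservationSeries
from .verification import SkillGrid

_ENGINE = "scipy"


# ---------------------------------------------------------------------------
# ForcingSeries
# ---------------------------------------------------------------------------


def forcing_to_csv(series: ForcingSeries, path) -> None:
    dates = cal.noleap_dates(series.start_year, len(series), series.start_doy)
    pd.DataFrame(
        {
            "date": dates,
            "temperature": series.temperature,
            "precipitation": series.precipitation,
        }
    ).to_csv(path, index=False)


def forcing_from_csv(path, subcatchment_id: str, calendar: str = cal.NOLEAP) -> ForcingSeries:
    df = pd.read_csv(path)
    y0, m0, d0 = (int(p) for p in str(df["date"].iloc[0]).split("-"))
    return ForcingSeries(
        start_year=y0,
        temperature=df["temperature"].to_numpy(float),
        precipitation=df["precipitation"].to_numpy(float),
        subcatchment_id=subcatchment_id,
        calendar=calendar,
        start_doy=cal.doy_of(m0, d0),
    )


def forcing_to_netcdf(series: ForcingSeries, path) -> None:
    ds = xr.Dataset(
        {
            "temperature": ("time", series.temperature),
            "precipitation": ("time", series.precipitation),
        },
        attrs={
            "start_year": series.start_year,
            "start_doy": series.start_doy,
            "calendar": series.calendar,
            "subcatchment_id": series.subcatchment_id,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def forcing_from_netcdf(path) -> ForcingSeries:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ForcingSeries(
            start_year=int(ds.attrs["start_year"]),
            temperature=ds["temperature"].values.copy(),
            precipitation=ds["precipitation"].values.copy(),
            subcatchment_id=str(ds.attrs["subcatchment_id"]),
            calendar=str(ds.attrs["calendar"]),
            start_doy=int(ds.attrs["start_doy"]),
        )


# ---------------------------------------------------------------------------
# EnsembleForecast
# ---------------------------------------------------------------------------


def ensemble_to_netcdf(fc: EnsembleForecast, path, provenance: str = "raw") -> None:
    ds = xr.Dataset(
        {fc.variable: (("member", "time"), fc.members)},
        attrs={
            "init_year": fc.init_year,
            "init_month": fc.init_month,
            "variable": fc.variable,
            "subcatchment_id": fc.subcatchment_id,
            "provenance": provenance,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def ensemble_from_netcdf(path) -> EnsembleForecast:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        var = str(ds.attrs["variable"])
        return EnsembleForecast(
            variable=var,
            init_year=int(ds.attrs["init_year"]),
            init_month=int(ds.attrs["init_month"]),
            members=ds[var].values.copy(),
            subcatchment_id=str(ds.attrs["subcatchment_id"]),
        )


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------


def observations_to_csv(obs: ObservationSeries, path) -> None:
    pd.DataFrame({"date": obs.dates, "day_index": obs.day_indices, "value": obs.values}).to_csv(
        path, index=False
    )


def observations_from_csv(path, variable: str) -> ObservationSeries:
    df = pd.read_csv(path)
    return ObservationSeries(
        day_indices=df["day_index"].to_numpy(int),
        dates=[str(d) for d in df["date"]],
        values=df["value"].to_numpy(float),
        variable=variable,
    )


# ---------------------------------------------------------------------------
# Skill grids
# ---------------------------------------------------------------------------


def skill_grid_to_csv(grid: SkillGrid, path) -> None:
    pd.DataFrame(grid.to_records()).to_csv(path, index=False)


def skill_grid_to_json(grid: SkillGrid, path) -> None:
    with open(path, "w") as fh:
        json.dump(grid.to_records(), fh, indent=2)


def skill_grid_heatmap(grid: SkillGrid, path) -> None:
    """PNG heatmap of the skill grid; negative CRPSS is floored at 0 for
    display only (stored values are untouched)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.clip(np.nan_to_num(grid.crpss, nan=0.0), 0.0, 0.8)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(shown, vmin=0, vmax=0.8, cmap="viridis", aspect="auto")
    ax.set_xlabel("lead month")
    ax.set_ylabel("initialization month")
    ax.set_xticks(range(grid.crpss.shape[1]), [str(i + 1) for i in range(grid.crpss.shape[1])])
    ax.set_yticks(range(12), [str(m) for m in range(1, 13)])
    ax.set_title(f"CRPSS — {grid.variable}" if grid.variable else "CRPSS")
    fig.colorbar(im, ax=ax, label="CRPSS (negative shown as 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
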