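"""Empirical quantile mapping (EQM) of forecast ensembles, leave-one-year-out.

EQM maps each forecast value onto the observed climate by matching empirical
quantiles: a value at forecast quantile p is replaced by the observed quantile
at the same p. Mappings are fitted separately for each (initialization month,
lead calendar month) cell, pooling all ensemble members and all days of that
calendar month across training years, and applied at the daily scale. The
training sample for a target year never includes that year (leave-one-year-out
cross-validation), so corrected hindcasts remain honest for skill assessment.

Conventions (common EQM practice): 99 equally spaced probabilities, linear
interpolation between fitted quantile nodes, constant-shift extrapolation in
the tails, a 0.1 mm d⁻¹ dry-day threshold for precipitation with the dry-day
frequency of the observations preserved through the mapping, and output
clamped at zero for precipitation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import (
    EnsembleForecast,
    ForcingSeries,
    HindcastArchive,
    PRECIPITATION,
    TEMPERATURE,
)

DRY_THRESHOLD = 0.1  # mm d⁻¹; smaller precipitation counts as dry
DEFAULT_N_Q = 99


@dataclass
class QuantileMap:
    """Matched forecast/observed quantiles for one conditioning cell."""

    variable: str
    fc_quantiles: np.ndarray
    obs_quantiles: np.ndarray
    init_month: int | None = None
    lead_month: int | None = None
    calendar_month: int | None = None
    tail_rule: str = "constant-shift"

    def __post_init__(self) -> None:
        self.fc_quantiles = np.asarray(self.fc_quantiles, dtype=float)
        self.obs_quantiles = np.asarray(self.obs_quantiles, dtype=float)
        if self.fc_quantiles.shape != self.obs_quantiles.shape or self.fc_quantiles.size < 2:
            raise ValueError("quantile sequences must have equal length ≥ 2")
        if np.any(np.diff(self.fc_quantiles) < 0) or np.any(np.diff(self.obs_quantiles) < 0):
            raise ValueError("quantile sequences must be non-decreasing")


def fit_eqm(
    fc_sample: np.ndarray,
    obs_sample: np.ndarray,
    variable: str = TEMPERATURE,
    n_q: int = DEFAULT_N_Q,
    **keys,
) -> QuantileMap:
    """Fit matched empirical quantiles at n_q probabilities (1/(n_q+1)..n_q/(n_q+1)).

    Degenerate (constant) samples fall back to a constant shift: both quantile
    sequences collapse to two equal nodes offset by the sample-mean difference,
    which the constant-shift tail rule then applies everywhere.
    """
    fc = np.asarray(fc_sample, dtype=float).ravel()
    obs = np.asarray(obs_sample, dtype=float).ravel()
    fc, obs = fc[np.isfinite(fc)], obs[np.isfinite(obs)]
    if fc.size == 0 or obs.size == 0:
        raise ValueError("empty training sample")
    if n_q < 2:
        raise ValueError("n_q must be at least 2")
    if variable == PRECIPITATION:
        fc = np.where(fc < DRY_THRESHOLD, 0.0, fc)
        obs = np.where(obs < DRY_THRESHOLD, 0.0, obs)
    probs = np.arange(1, n_q + 1) / (n_q + 1)
    fq = np.quantile(fc, probs)
    oq = np.quantile(obs, probs)
    if fq[-1] - fq[0] <= 0:  # constant forecast sample: constant-shift fallback
        shift = obs.mean() - fc.mean()
        fq = np.array([fc.mean(), fc.mean() + 1.0])
        oq = fq + shift
    return QuantileMap(variable=variable, fc_quantiles=fq, obs_quantiles=np.maximum.accumulate(oq),
                       **keys)


def apply_eqm(qmap: QuantileMap, values: np.ndarray) -> np.ndarray:
    """Correct values through the fitted map.

    Inside the fitted range: linear interpolation between matched quantile
    nodes. Outside: a constant shift equal to the correction at the nearest
    boundary node, so extreme values keep their distance from the sample edge.
    Precipitation output is clamped at zero and sub-threshold values are dried.
    """
    v = np.asarray(values, dtype=float)
    fq, oq = qmap.fc_quantiles, qmap.obs_quantiles
    if qmap.variable == PRECIPITATION and np.all(oq < DRY_THRESHOLD):
        return np.zeros_like(v)  # fully dry observed climate: everything maps dry
    corrected = np.interp(v, fq, oq)
    lo, hi = fq[0], fq[-1]
    corrected = np.where(v < lo, v + (oq[0] - lo), corrected)
    corrected = np.where(v > hi, v + (oq[-1] - hi), corrected)
    if qmap.variable == PRECIPITATION:
        corrected = np.where(v < DRY_THRESHOLD, 0.0, corrected)
        corrected = np.where(corrected < DRY_THRESHOLD, 0.0, corrected)
        corrected = np.maximum(corrected, 0.0)
    return corrected


def correct_archive_loo(
    archive: HindcastArchive,
    pseudo_obs: dict[str, ForcingSeries] | ForcingSeries,
    n_q: int = DEFAULT_N_Q,
) -> HindcastArchive:
    """Leave-one-year-out EQM correction of a whole hindcast archive.

    For each (variable, sub-catchment, init month, lead calendar month, target
    year): the training forecast sample pools all members and all days of that
    lead calendar month from every archive year except the target year; the
    training observation sample pools the pseudo-observation days of that
    calendar month in every archive year except the target year. The fitted
    map is applied to the target year's member days of that calendar month.
    Output has exactly the shape of the input archive.
    """
    if len(archive.years) < 2:
        raise ValueError("leave-one-year-out requires an archive spanning at least 2 years")
    if isinstance(pseudo_obs, ForcingSeries):
        pseudo_obs = {sc: pseudo_obs for sc in archive.subcatchments}

    corrected: dict[tuple[str, str, int, int], EnsembleForecast] = {}
    for sc in archive.subcatchments:
        truth = pseudo_obs[sc]
        t_months, t_years = truth.months, truth.years
        for variable in archive.variables:
            t_values = truth.variable(variable)
            for init_month in archive.init_months:
                cells = {
                    year: archive.get(variable, sc, year, init_month) for year in archive.years
                }
                day_months = next(iter(cells.values())).months  # same for all years
                for year, fc in cells.items():
                    new_members = fc.members.copy()
                    for m in np.unique(day_months):
                        train_fc = np.concatenate([
                            other.members[:, day_months == m].ravel()
                            for y, other in cells.items()
                            if y != year
                        ])
                        # obs days of calendar month m in archive years except target
                        obs_sel = (t_months == m) & (t_years != year) & np.isin(
                            t_years, archive.years
                        )
                        train_obs = t_values[obs_sel]
                        qmap = fit_eqm(train_fc, train_obs, variable=variable, n_q=n_q,
                                       init_month=init_month, calendar_month=int(m))
                        sel = day_months == m
                        new_members[:, sel] = apply_eqm(qmap, fc.members[:, sel])
                    corrected[(variable, sc, year, init_month)] = replace(
                        fc, members=np.maximum(new_members, 0.0)
                        if variable == PRECIPITATION else new_members
                    )
    return replace(archive, forecasts=corrected)
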