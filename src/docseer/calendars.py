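"""Calendar arithmetic for daily forcing series.

The forecasting chain runs on a fixed 365-day ("noleap365") calendar by
default: every year has the same month lengths, which makes warm-up windows,
lead-month boundaries and the 215-day prediction horizon exact integers.
A Gregorian mode is provided for user-supplied observation data; it delegates
to pandas.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

NOLEAP = "noleap365"
GREGORIAN = "gregorian"

DAYS_PER_YEAR = 365

#: Month lengths in the noleap calendar (January..December).
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Day-of-year (0-based) on which each month starts.
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])

#: Calendar month (1..12) for each day of a noleap year, shape (365,).
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)

#: Day horizon of a seasonal forecast: seven lead months cover at most 215 days.
PREDICTION_HORIZON_DAYS = 215


def validate_calendar(calendar: str) -> str:
    if calendar not in (NOLEAP, GREGORIAN):
        raise ValueError(f"unknown calendar {calendar!r}; expected {NOLEAP!r} or {GREGORIAN!r}")
    return calendar


def doy_of(month: int, day: int) -> int:
    """0-based day-of-year of (month, day) in the noleap calendar."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= MONTH_LENGTHS[month - 1]:
        raise ValueError(f"day {day} out of range for month {month}")
    return int(MONTH_STARTS[month - 1] + day - 1)


def day_index(start_year: int, year: int, month: int = 1, day: int = 1) -> int:
    """Index of (year, month, day) into a daily series starting 1 Jan of start_year."""
    return (year - start_year) * DAYS_PER_YEAR + doy_of(month, day)


def date_of_index(start_year: int, index: int) -> tuple[int, int, int]:
    """Inverse of :func:`day_index`: (year, month, day) of a day index."""
    year, doy = divmod(int(index), DAYS_PER_YEAR)
    month = int(MONTH_OF_DOY[doy])
    day = doy - int(MONTH_STARTS[month - 1]) + 1
    return start_year + year, month, day


def month_of_indices(n_days: int, start_doy: int = 0) -> np.ndarray:
    """Calendar month (1..12) for each of n_days consecutive noleap days."""
    doys = (start_doy + np.arange(n_days)) % DAYS_PER_YEAR
    return MONTH_OF_DOY[doys]


def year_of_indices(n_days: int, start_year: int, start_doy: int = 0) -> np.ndarray:
    """Calendar year for each of n_days consecutive noleap days."""
    return start_year + (start_doy + np.arange(n_days)) // DAYS_PER_YEAR


def lead_months(init_month: int, n_leads: int = 7) -> np.ndarray:
    """Calendar months of leads 1..n_leads; lead 1 is the initialization month."""
    return (init_month - 1 + np.arange(n_leads)) % 12 + 1


def noleap_dates(start_year: int, n_days: int, start_doy: int = 0) -> list[str]:
    """ISO-like date labels for consecutive noleap days (for CSV output)."""
    out = []
    for i in range(n_days):
        y, m, d = date_of_index(start_year, start_doy + i)
        out.append(f"{y:04d}-{m:02d}-{d:02d}")
    return out


def gregorian_index(dates: _dt.date | str, periods: int) -> pd.DatetimeIndex:
    """Daily DatetimeIndex for Gregorian-calendar user data."""
    return pd.date_range(start=dates, periods=periods, freq="D")
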