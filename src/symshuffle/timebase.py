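"""Idealised model calendar: 30-day months, 360-day years.

All simulation time is measured in days from the start of the run, with
``t = 0`` being the first day of January of year 0.  Month indices are
1-based (January = 1), so July spans days 181-210 of each year when counted
1-based, i.e. ``t`` in ``[180, 210)`` here.
"""

from __future__ import annotations

import math

DAYS_PER_MONTH = 30
MONTHS_PER_YEAR = 12
DAYS_PER_YEAR = DAYS_PER_MONTH * MONTHS_PER_YEAR  # 360

#: Month blocks considered "winter/spring peak season" in summaries
#: (December through April).
PEAK_SEASON_MONTHS = (12, 1, 2, 3, 4)


def month_of_day(t: float) -> int:
    """1-based month index (1..12) containing day ``t`` (t >= 0)."""
    if t < 0:
        raise ValueError(f"day index must be non-negative, got {t}")
    doy = math.floor(t) % DAYS_PER_YEAR
    return doy // DAYS_PER_MONTH + 1


def year_of_day(t: float) -> int:
    """0-based simulation year containing day ``t``."""
    if t < 0:
        raise ValueError(f"day index must be non-negative, got {t}")
    return math.floor(t) // DAYS_PER_YEAR


def month_midpoint(month: int, year: int = 0) -> float:
    """Day index at the middle of a 1-based month (used to place monthly
    climatology samples on the time axis)."""
    if not 1 <= month <= MONTHS_PER_YEAR:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year * DAYS_PER_YEAR + (month - 0.5) * DAYS_PER_MONTH
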