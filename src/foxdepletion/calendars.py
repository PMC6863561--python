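"""Calendar conventions for the two-weekly time-step.

A calendar year is divided into 26 two-week steps. Week ``w`` of a year is
``ceil(day_of_year / 7)`` and step ``s`` covers weeks ``2s - 1 .. 2s``; the
odd days at the end of the year (day 365 and, in leap years, 366) are folded
into step 26. Month-anchored windows used by the management metrics are
expressed in these step indices (1-based):

* pre-breeding (February): steps 3-4 (weeks 5-8)
* gamebird nesting period (weeks 10-30, March-July): steps 5-15
* April-July (seasonal-immigration window, weeks 14-30): steps 7-15
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

STEPS_PER_YEAR = 26

FEBRUARY_STEPS = (3, 4)
NESTING_STEPS = tuple(range(5, 16))
APRIL_JULY_STEPS = tuple(range(7, 16))


def week_of_year(day_of_year: int) -> int:
    """Week index (1..52) for a 1-based day of year; days > 364 fold into week 52."""
    if day_of_year < 1:
        raise ValueError(f"day_of_year must be >= 1, got {day_of_year}")
    return min((day_of_year + 6) // 7, 52)


def step_of_week(week: int) -> int:
    """Two-week step (1..26) containing calendar week ``week`` (1..52)."""
    if not 1 <= week <= 52:
        raise ValueError(f"week must be in 1..52, got {week}")
    return (week + 1) // 2


def step_of_date(date: _dt.date) -> tuple[int, int]:
    """(year, step) for a calendar date under the package binning convention."""
    return date.year, step_of_week(week_of_year(date.timetuple().tm_yday))


def step_grid(start_year: int, n_steps: int, start_step: int = 1):
    """Arrays (year, step_of_year) for ``n_steps`` consecutive two-week steps."""
    idx = np.arange(n_steps) + (start_step - 1)
    years = start_year + idx // STEPS_PER_YEAR
    steps = idx % STEPS_PER_YEAR + 1
    return years, steps
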