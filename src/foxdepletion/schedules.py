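"""Within-year recruitment schedule for weaned fox cubs.

The observable population a lamping index can see comprises adults plus cubs
active away from the breeding earth after weaning. Rather than recruiting a
whole cohort in one step, cub recruitment is spread over the season with a
schedule ``w_t`` (one weight per two-week step of the year, summing to 1)
derived from a logistic distribution of conception dates shifted by gestation
and the birth-to-recruitment (weaning) interval.

Cubs culled at breeding earths are of pre-weaning age, so an observed cub cull
cannot be subtracted from the observable population in the step it was
recorded (those cubs have not recruited yet). Instead the annual cub-cull
total is redistributed across the recruitment steps of its year in proportion
to ``w_t``, which conserves the annual total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import logistic

from .calendars import STEPS_PER_YEAR

__all__ = [
    "ConceptionModel",
    "RecruitmentSchedule",
    "build_weaning_schedule",
    "redistribute_cub_cull",
]


@dataclass(frozen=True)
class ConceptionModel:
    """Logistic model of conception timing plus fixed phenological offsets.

    Parameters
    ----------
    location_week
        Calendar week (continuous, week-of-year units) of median conception.
        The default puts median conception in early February so that births
        peak mid-March to mid-April given the gestation offset.
    scale_weeks
        Scale of the logistic conception distribution, in weeks.
    gestation_weeks
        Conception-to-birth offset (red fox gestation is about 52 days).
    weaning_weeks
        Birth-to-recruitment offset; cubs are fully weaned and active away
        from the earth by about eight weeks of age.
    """

    location_week: float = 6.0
    scale_weeks: float = 1.2
    gestation_weeks: float = 7.4
    weaning_weeks: float = 8.0

    def __post_init__(self) -> None:
        if self.scale_weeks < 0:
            raise ValueError(f"scale_weeks must be >= 0, got {self.scale_weeks}")
        if self.gestation_weeks < 0 or self.weaning_weeks < 0:
            raise ValueError("gestation_weeks and weaning_weeks must be >= 0")

    @property
    def recruitment_location_week(self) -> float:
        return self.location_week + self.gestation_weeks + self.weaning_weeks


@dataclass(frozen=True)
class RecruitmentSchedule:
    """Normalized within-year recruitment weights on the two-week grid.

    ``w`` has length 26 (one entry per step of a calendar year), is
    nonnegative and sums to one; ``support`` is the index range (1-based,
    inclusive) of the nonzero steps.
    """

    w: np.ndarray
    support: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (STEPS_PER_YEAR,):
            raise ValueError(f"w must have length {STEPS_PER_YEAR}, got {w.shape}")
        if np.any(w < 0):
            raise ValueError("recruitment weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"recruitment weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "w", w)
        nz = np.nonzero(w)[0]
        object.__setattr__(self, "support", (int(nz[0]) + 1, int(nz[-1]) + 1))

    def shifted(self, k_steps: int) -> "RecruitmentSchedule":
        """Schedule moved ``k_steps`` two-week steps later (negative: earlier).

        Used by the sensitivity suite (cubs born on average earlier/later).
        Mass may not cross the year boundary.
        """
        lo, hi = self.support
        if not (1 <= lo + k_steps and hi + k_steps <= STEPS_PER_YEAR):
            raise ValueError(
                f"shift by {k_steps} steps moves schedule support {self.support} "
                f"outside the calendar year"
            )
        return RecruitmentSchedule(np.roll(self.w, k_steps))


def build_weaning_schedule(
    cm: ConceptionModel,
    steps_per_year: int = STEPS_PER_YEAR,
    min_weight: float = 0.01,
) -> RecruitmentSchedule:
    """Discretize the shifted conception distribution onto the two-week grid.

    The recruitment-time distribution is the conception logistic shifted by
    gestation plus weaning. Each step's weight is the CDF mass falling in
    that step's two-week window; because the logistic has unbounded support,
    steps receiving less than ``min_weight`` of the mass are zeroed and the
    remainder renormalized, giving a schedule with compact within-year
    support. A degenerate (``scale_weeks == 0``) model yields a point mass in
    the step containing the median recruitment week.

    Raises
    ------
    ValueError
        If appreciable schedule mass falls outside the calendar year
        (recruitment cannot wrap across 31 December).
    """
    if steps_per_year != STEPS_PER_YEAR:
        raise ValueError("only the 26-step two-weekly grid is supported")
    loc = cm.recruitment_location_week
    edges = 2.0 * np.arange(steps_per_year + 1)  # step s covers weeks (2s-2, 2s]
    if cm.scale_weeks == 0.0:
        w = np.zeros(steps_per_year)
        step = int(np.searchsorted(edges, loc, side="left"))  # 1-based step
        if not 1 <= step <= steps_per_year:
            raise ValueError(
                f"degenerate schedule at week {loc:.2f} lies outside the year "
                f"(location_week={cm.location_week}, "
                f"gestation_weeks={cm.gestation_weeks}, "
                f"weaning_weeks={cm.weaning_weeks})"
            )
        w[step - 1] = 1.0
        return RecruitmentSchedule(w)

    cdf = logistic.cdf(edges, loc=loc, scale=cm.scale_weeks)
    outside = cdf[0] + (1.0 - cdf[-1])
    if outside > min_weight:
        raise ValueError(
            f"{outside:.3f} of the recruitment mass falls outside the calendar "
            f"year for location_week={cm.location_week}, "
            f"scale_weeks={cm.scale_weeks}, gestation_weeks={cm.gestation_weeks}, "
            f"weaning_weeks={cm.weaning_weeks}; spring recruitment cannot wrap "
            f"across 31 December"
        )
    w = np.diff(cdf)
    w[w < min_weight] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("all schedule mass fell below min_weight")
    return RecruitmentSchedule(w / total)


def redistribute_cub_cull(
    observed_C: np.ndarray,
    sched: RecruitmentSchedule,
    years: np.ndarray,
    steps_of_year: np.ndarray,
) -> np.ndarray:
    """Spread each year's observed cub-cull total over its recruitment steps.

    Within each calendar year the output is ``w_t`` times the annual total of
    the observed cub cull; annual totals are conserved exactly. If a series
    covers only part of a year's recruitment window, the weights are
    renormalized over the covered steps so that conservation still holds.

    Parameters
    ----------
    observed_C
        Observed cub-cull densities (cub km^-2) per series step.
    sched
        Recruitment schedule.
    years, steps_of_year
        Calendar arrays aligned with ``observed_C`` (step_of_year is 1-based).
    """
    obs = np.asarray(observed_C, dtype=float)
    years = np.asarray(years)
    steps_of_year = np.asarray(steps_of_year)
    if not (obs.shape == years.shape == steps_of_year.shape):
        raise ValueError("observed_C, years and steps_of_year must be aligned")
    if np.any(obs < 0):
        raise ValueError("observed cub-cull densities must be nonnegative")

    out = np.zeros_like(obs)
    for y in np.unique(years):
        mask = years == y
        total = obs[mask].sum()
        if total == 0.0:
            continue
        w_cov = sched.w[steps_of_year[mask] - 1]
        cov = w_cov.sum()
        if cov <= 0.0:
            raise ValueError(
                f"year {y} has a cub cull of {total:g} but the series covers "
                f"no recruitment step of that year"
            )
        out[mask] = total * w_cov / cov
    return out
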