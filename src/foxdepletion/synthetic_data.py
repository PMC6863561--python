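"""Operating model: simulated estates with known truth, plus the data screen.

The generator emulates the features of gamekeeper culling diaries that drive
the estimator: seasonal lamping effort (lowest in summer when crop cover
makes lamping unproductive, highest after harvest), Poisson detections
proportional to effort times density, a lamping cull that is a Bernoulli
thinning of detections (about 30% of detected foxes are killed), additional
non-lamping culls (snaring etc., weighted toward winter and calibrated so
lamping accounts for about two-thirds of the adult cull), an annual cub cull
at breeding earths, and lognormal process error with s.d. 0.2.

It also implements the data-requirement screen used to decide whether a
series carries enough information to identify the parameters: enough
recruitment periods, effort within them, a minimum of lamping effort per
year, no long gaps, and consistent effort at the start of the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calendars import STEPS_PER_YEAR, step_grid
from .model_core import (
    DENSITY_FLOOR,
    EstateSeries,
    ModelParams,
    StateTrajectory,
    init_state,
    recruit,
    step_density,
)
from .schedules import RecruitmentSchedule

__all__ = [
    "OperatingTruth",
    "EffortPattern",
    "RequirementReport",
    "generate_effort",
    "simulate_estate",
    "check_data_requirements",
]

#: season index per step-of-year (0 winter, 1 spring, 2 summer, 3 autumn);
#: step 1 starts in January.
_SEASON_OF_STEP = np.array(
    [0] * 4 + [1] * 7 + [2] * 6 + [3] * 6 + [0] * 3
)  # steps 1-4 winter, 5-11 spring, 12-17 summer, 18-23 autumn, 24-26 winter

#: winter-weighted multiplier for non-lamping culls (snaring is a
#: winter-biased activity); mean 1 across the year.
_OTHER_CULL_SEASON = np.array([1.5, 1.0, 0.5, 1.0])


@dataclass(frozen=True)
class EffortPattern:
    """Seasonal lamping-effort design for a simulated estate.

    ``weekly_hours`` gives mean lamping hours per week for (winter, spring,
    summer, autumn); ``summer_attenuation`` further scales the summer mean
    (1.0 = no attenuation). ``noise_cv`` is the lognormal CV of step-level
    effort. ``gap`` optionally zeroes a run of steps, as (start_index,
    n_steps), to emulate a recording gap.
    """

    weekly_hours: tuple = (6.0, 4.0, 2.0, 6.0)
    summer_attenuation: float = 0.7
    noise_cv: float = 0.3
    years: int = 4
    gap: tuple | None = None

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.weekly_hours) or len(self.weekly_hours) != 4:
            raise ValueError("weekly_hours must be four nonnegative values")
        if not 0 <= self.summer_attenuation <= 1:
            raise ValueError("summer_attenuation must be in [0, 1]")


@dataclass(frozen=True)
class OperatingTruth:
    """Known truth for one simulated estate.

    ``kill_prob`` is the probability a detected fox is culled (empirically
    about 0.30 on the contributing estates); ``other_cull_ratio`` scales
    expected non-lamping culls relative to expected lamping culls (0.515
    makes lamping about 66% of the adult cull); ``cub_cull_fraction`` is the
    fraction of a year's cub production removed at earths.
    """

    params: ModelParams
    kill_prob: float = 0.30
    other_cull_ratio: float = 0.515
    cub_cull_fraction: float = 0.10
    area_km2: float = 8.4  # mean estate size in the study region

    def __post_init__(self) -> None:
        if not 0.0 <= self.kill_prob <= 1.0:
            raise ValueError("kill_prob must be in [0, 1]")
        if self.other_cull_ratio < 0 or self.cub_cull_fraction < 0:
            raise ValueError("cull intensities must be nonnegative")
        if not 0.0 <= self.cub_cull_fraction <= 1.0:
            raise ValueError("cub_cull_fraction must be in [0, 1]")


def generate_effort(pattern: EffortPattern, seed: int = 0) -> np.ndarray:
    """Per-step lamping hours over ``pattern.years`` calendar years.

    Step effort is 2 weeks x the seasonal weekly mean (summer additionally
    attenuated), with multiplicative lognormal noise of CV ``noise_cv``;
    mean-one noise so the seasonal profile is preserved in expectation.
    """
    rng = np.random.default_rng(seed)
    n = pattern.years * STEPS_PER_YEAR
    _, steps = step_grid(1996, n)
    season = _SEASON_OF_STEP[steps - 1]
    hours = 2.0 * np.asarray(pattern.weekly_hours)[season]
    hours = np.where(season == 2, hours * pattern.summer_attenuation, hours)
    if pattern.noise_cv > 0:
        sig = np.sqrt(np.log1p(pattern.noise_cv**2))
        hours = hours * rng.lognormal(-sig**2 / 2.0, sig, size=n)
    if pattern.gap is not None:
        start, length = pattern.gap
        hours[start:start + length] = 0.0
    return hours


def simulate_estate(
    truth: OperatingTruth,
    effort: np.ndarray,
    sched: RecruitmentSchedule,
    seed: int = 0,
    start_year: int = 1996,
) -> tuple[EstateSeries, StateTrajectory]:
    """Run the state and observation models generatively for one estate.

    Detections are Poisson(d E_t N_t); the lamping cull is a binomial
    thinning of detections at ``kill_prob`` (so culled never exceed detected
    in any step); non-lamping culls are Poisson with a winter-biased seasonal
    weight; the cub cull is drawn binomially from the year's expected cub
    production and recorded in the first recruitment step of the year, then
    spread over the recruitment schedule before it enters the dynamics (the
    same redistribution the estimator applies).
    """
    p = truth.params
    area = truth.area_km2
    rng = np.random.default_rng(seed)
    effort = np.asarray(effort, dtype=float)
    T = len(effort)
    years, steps = step_grid(start_year, T)
    w = sched.w[steps - 1]
    first_recruit = sched.support[0]

    mean_effort = effort.mean()
    season_mult = _OTHER_CULL_SEASON[_SEASON_OF_STEP[steps - 1]]

    N = np.empty(T)
    J = np.empty(T)
    eps = rng.normal(0.0, p.sigma_p, size=T)
    Y = np.zeros(T, dtype=np.int64)
    L = np.zeros(T)
    S = np.zeros(T)
    C_obs = np.zeros(T)
    C = np.zeros(T)  # redistributed cub cull driving the dynamics

    floored = 0
    for t in range(T):
        if t == 0:
            N[t] = init_state(p, eps[0])
        else:
            N[t] = step_density(N[t - 1], J[t - 1], L[t - 1], S[t - 1], p, eps[t])
        if N[t] <= DENSITY_FLOOR:
            floored += 1

        # annual cub cull, decided at the first recruitment step of the year
        if steps[t] == first_recruit and truth.cub_cull_fraction > 0:
            production = p.r * N[t] * max(1.0 - N[t] / p.K, 0.0) * area
            n_cubs = rng.binomial(
                max(int(round(production)), 0), truth.cub_cull_fraction
            )
            C_obs[t] = n_cubs / area
            in_year = years == years[t]
            wy = w * in_year
            if wy.sum() > 0:
                C[in_year] = C_obs[t] * wy[in_year] / wy.sum()

        J[t] = recruit(N[t], C[t], w[t], p)

        # observation and cull channels
        if effort[t] > 0:
            Y[t] = rng.poisson(p.d * effort[t] * N[t])
            L[t] = rng.binomial(Y[t], truth.kill_prob) / area
        lam_other = (
            truth.other_cull_ratio
            * truth.kill_prob * p.d * mean_effort * N[t]
            * season_mult[t] * area
        )
        S[t] = rng.poisson(lam_other) / area

    if floored > 10:
        import logging

        logging.getLogger(__name__).info(
            "simulated estate hit the density floor in %d/%d steps", floored, T
        )

    series = EstateSeries(
        E=effort, Y=Y, L=L, S=S, C_obs=C_obs, area=area,
        years=years, steps=steps, estate="synthetic",
    )
    return series, StateTrajectory(N=N, J=J, eps=eps)


@dataclass
class RequirementReport:
    passed: bool
    reasons: list = field(default_factory=list)
    checks: dict = field(default_factory=dict)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_data_requirements(
    series: EstateSeries, sched: RecruitmentSchedule
) -> RequirementReport:
    """Screen a series against the identifiability requirements.

    Rules (recruitment period = steps where w_t > 0):

    * at least three cub recruitment periods within the series span;
    * at least two effort-positive steps in each covered recruitment period;
    * at least eight weeks (four effort-positive two-week steps) of lamping
      per covered year;
    * no gap between effort-positive steps longer than nine months
      (19 two-week steps);
    * consistent effort at the start: at least one effort-positive step in
      each of the first three four-week (two-step) windows.
    """
    w = sched.w[series.steps - 1]
    has_effort = series.E > 0
    checks: dict[str, bool] = {}
    reasons: list[str] = []

    years = np.unique(series.years)
    recruit_years = []
    for y in years:
        in_y = series.years == y
        if (w[in_y] > 0).sum() >= len(np.nonzero(sched.w)[0]):
            recruit_years.append(y)
    checks["recruitment_periods"] = len(recruit_years) >= 3
    if not checks["recruitment_periods"]:
        reasons.append(
            f"only {len(recruit_years)} complete cub recruitment periods "
            "covered (need >= 3)"
        )

    bad = [
        int(y) for y in recruit_years
        if (has_effort & (series.years == y) & (w > 0)).sum() < 2
    ]
    checks["recruitment_effort"] = not bad
    if bad:
        reasons.append(
            f"fewer than two effort-positive steps in the recruitment period "
            f"of year(s) {bad}"
        )

    low = [
        int(y) for y in years
        if (has_effort & (series.years == y)).sum() < 4
        and (series.years == y).sum() >= STEPS_PER_YEAR // 2
    ]
    checks["annual_effort"] = not low
    if low:
        reasons.append(
            f"less than eight weeks of lamping effort in year(s) {low}"
        )

    idx = np.nonzero(has_effort)[0]
    if len(idx) == 0:
        gap = len(series)
    else:
        boundaries = np.concatenate([[-1], idx, [len(series)]])
        gap = int(np.max(np.diff(boundaries)) - 1)
    checks["max_gap"] = gap <= 19
    if not checks["max_gap"]:
        reasons.append(
            f"gap of {gap} steps ({gap * 2} weeks) without lamping effort "
            "exceeds nine months"
        )

    start_ok = all(has_effort[2 * k:2 * k + 2].any() for k in range(3))
    checks["initial_effort"] = bool(start_ok) and len(series) >= 6
    if not checks["initial_effort"]:
        reasons.append(
            "lamping effort is not consistent over the first three months"
        )

    return RequirementReport(passed=all(checks.values()), reasons=reasons,
                             checks=checks)
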