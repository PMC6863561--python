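"""Simulation-estimation harness: parameter-recovery bias and coverage.

Sets of estates are simulated from the operating model with truth drawn from
the informative priors, fitted with either informative or vague priors, and
the posterior medians compared against the known truth. The headline
quantity is the mean percent relative bias of posterior-median density
(mean over steps within a replicate, then over replicates); per-parameter
bias and 80/95% credible-interval coverage are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ConvergenceWarning, MCMCConfig, fit, summarize
from .model_core import PARAM_NAMES, EstateSeries, StateTrajectory
from .priors import PriorSet, build_priors
from .schedules import ConceptionModel, RecruitmentSchedule, build_weaning_schedule
from .synthetic_data import (
    EffortPattern,
    OperatingTruth,
    check_data_requirements,
    generate_effort,
    simulate_estate,
)

__all__ = [
    "SimEstResult",
    "relative_bias",
    "simulate_population_set",
    "run_simest",
    "ci_coverage",
]

#: replicates whose worst parameter R-hat exceeds this are re-run once with a
#: fresh seed, then excluded; looser than the headline 1.01 because
#: desk-scale chains carry more Monte-Carlo noise in the diagnostic itself.
RHAT_EXCLUDE = 1.1


def relative_bias(estimate, truth) -> float:
    """Mean percent relative bias, 100 * (estimate - truth) / truth.

    Vector inputs are averaged elementwise (mean over steps for a density
    trajectory).
    """
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimate and truth must have the same shape")
    if np.any(tru <= 0):
        raise ValueError("truth must be strictly positive")
    return float(np.mean(100.0 * (est - tru) / tru))


#: truth-generating distributions for the operating model, calibrated to the
#: estate-level estimates culled shooting estates actually exhibit rather
#: than to the pre-data priors. The prior for v (median 0.093 fox km^-2 per
#: two-week step) averages over all landscape types including uplands;
#: estates under study-intensity culling show immigration several-fold
#: higher, and realized search rates well below the d prior's median.
#: Drawing truths from the priors therefore yields populations that either
#: collapse under diary-scale lamping effort or yield detection series far
#: sparser than real diaries; these ranges reproduce the quoted data
#: features (suppression to 20-90% of K, tens of culls and one-to-several
#: hundred detections per year).
TRUTH_RANGES = {
    "K": (2.0, 8.5),  # uniform, fox km^-2 (span of estate-level estimates)
    "N0_frac": (0.2, 1.0),  # uniform fraction of K
    "v": (0.25, 0.84),  # lognormal (median per 2wk, CV): estate-level scale
    "d": (0.35, 0.50),  # lognormal (median km^2 hr^-1, CV): realized rates
}


def draw_truth_params(priors: PriorSet, rng: np.random.Generator):
    """One truth parameter vector for the operating model.

    r and M are drawn from the informative priors (estate-level estimates
    sit inside those priors); K, N0, v and d are drawn from
    :data:`TRUTH_RANGES`, which emulate the study estates (see note above).
    """
    p = priors.sample_params(rng)
    K = float(rng.uniform(*TRUTH_RANGES["K"]))
    N0 = float(K * rng.uniform(*TRUTH_RANGES["N0_frac"]))
    med, cv = TRUTH_RANGES["v"]
    v = float(rng.lognormal(np.log(med), np.sqrt(np.log1p(cv**2))))
    med, cv = TRUTH_RANGES["d"]
    d = float(rng.lognormal(np.log(med), np.sqrt(np.log1p(cv**2))))
    return p.with_(K=K, N0=N0, v=v, d=d)


def simulate_population_set(
    n_pops: int,
    series_years: int = 4,
    seed: int = 0,
    truth_priors: PriorSet | None = None,
    sched: RecruitmentSchedule | None = None,
    pattern: EffortPattern | None = None,
    require_screen_pass: bool = True,
    max_attempts: int = 20,
) -> list[tuple[OperatingTruth, EstateSeries, StateTrajectory]]:
    """Draw ``n_pops`` operating-model estates with truth from the priors.

    Truth parameter vectors are drawn from the informative priors (the
    generator's study conditions); each simulated series is redrawn with a
    fresh sub-seed until it passes the data-requirement screen.
    """
    truth_priors = truth_priors or build_priors("informative")
    sched = sched or build_weaning_schedule(ConceptionModel())
    # Seasonal lamping effort (lowest in summer) at an intensity which,
    # combined with draw_truth_params, reproduces the study's quoted
    # features: suppression spanning roughly 20-90% of K, detection rates
    # under one fox per lamping hour, and realistic annual cull counts.
    pattern = pattern or EffortPattern(
        weekly_hours=(1.0, 0.7, 0.35, 1.0), years=series_years
    )
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_pops):
        rng = np.random.default_rng(child)
        for _ in range(max_attempts):
            params = draw_truth_params(truth_priors, rng)
            truth = OperatingTruth(params=params)
            sub = int(rng.integers(2**31 - 1))
            effort = generate_effort(pattern, seed=sub)
            series, traj = simulate_estate(truth, effort, sched, seed=sub + 1)
            if not require_screen_pass:
                break
            if check_data_requirements(series, sched).passed:
                break
        else:
            raise RuntimeError(
                f"no screen-passing series generated in {max_attempts} attempts"
            )
        out.append((truth, series, traj))
    return out


@dataclass
class SimEstResult:
    replicates: pd.DataFrame
    mean_density_bias: float
    param_bias: pd.Series
    coverage80: pd.Series
    coverage95: pd.Series
    n_excluded: int
    prior_mode: str


def run_simest(
    n_pops: int = 20,
    prior_mode: str = "informative",
    series_years: int = 4,
    cfg: MCMCConfig | None = None,
    seed: int = 0,
    populations=None,
    sched: RecruitmentSchedule | None = None,
    rhat_exclude: float = RHAT_EXCLUDE,
) -> SimEstResult:
    """Repeated simulate-fit cycles with known truth.

    ``populations`` may carry a pre-simulated set (so informative and vague
    fits can share identical estates); otherwise ``n_pops`` estates are
    drawn. Replicates that fail the R-hat gate are refitted once with a
    fresh seed and excluded if still non-converged.
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    sched = sched or build_weaning_schedule(ConceptionModel())
    cfg = cfg or MCMCConfig.profile("standard", seed=seed)
    fit_priors = build_priors(prior_mode)
    if populations is None:
        populations = simulate_population_set(
            n_pops, series_years=series_years, seed=seed, sched=sched
        )

    rows = []
    n_excluded = 0
    for i, (truth, series, traj) in enumerate(populations):
        row, ok = _fit_one(series, traj, truth, fit_priors, sched, cfg, i,
                           rhat_exclude=rhat_exclude)
        if not ok:
            row, ok = _fit_one(
                series, traj, truth, fit_priors, sched, cfg, i, retry=True,
                rhat_exclude=rhat_exclude,
            )
        if not ok:
            n_excluded += 1
            continue
        rows.append(row)

    if not rows:
        raise RuntimeError("all replicates failed the convergence gate")
    reps = pd.DataFrame(rows)
    cov80 = pd.Series(
        {p: float(reps[f"{p}_cov80"].mean()) for p in PARAM_NAMES}
    )
    cov95 = pd.Series(
        {p: float(reps[f"{p}_cov95"].mean()) for p in PARAM_NAMES}
    )
    param_bias = pd.Series(
        {p: float(reps[f"{p}_bias"].mean()) for p in PARAM_NAMES}
    )
    return SimEstResult(
        replicates=reps,
        mean_density_bias=float(reps["density_bias"].mean()),
        param_bias=param_bias,
        coverage80=cov80,
        coverage95=cov95,
        n_excluded=n_excluded,
        prior_mode=prior_mode,
    )


def _fit_one(series, traj, truth, fit_priors, sched, cfg, index, retry=False,
             rhat_exclude=RHAT_EXCLUDE):
    seed = cfg.seed + 1000 * index + (500_000 if retry else 0)
    cfg_i = MCMCConfig(
        n_chains=cfg.n_chains, burn_in=cfg.burn_in, thin=cfg.thin,
        n_recorded=cfg.n_recorded, seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        post = fit(series, fit_priors, sched, cfg_i, check_requirements=False)
    summ = summarize(post)
    max_rhat = float(post.rhat[list(PARAM_NAMES)].max())
    ok = max_rhat <= rhat_exclude

    N_med = np.median(post.N.reshape(-1, len(series)), axis=0)
    row = {
        "replicate": index,
        "max_rhat": max_rhat,
        "density_bias": relative_bias(N_med, traj.N),
    }
    for p in PARAM_NAMES:
        tru = getattr(truth.params, p)
        t = summ.table.loc[p]
        row[f"{p}_true"] = tru
        row[f"{p}_med"] = t["median"]
        row[f"{p}_bias"] = relative_bias(t["median"], tru)
        row[f"{p}_cov80"] = bool(t["q10"] <= tru <= t["q90"])
        row[f"{p}_cov95"] = bool(t["q2.5"] <= tru <= t["q97.5"])
    return row, ok


def ci_coverage(results: SimEstResult, level: float = 0.80) -> pd.Series:
    """Observed per-parameter coverage rate of central credible intervals."""
    if level == 0.80:
        return results.coverage80
    if level == 0.95:
        return results.coverage95
    raise ValueError("level must be 0.80 or 0.95")
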