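"""Prior distributions for the depletion-model parameters.

The informative set encodes external knowledge of fox demography:

* ``v`` (immigration): lognormal, median 2.41/26 fox km^-2 per two-week step
  (2.41 fox km^-2 yr^-1 from a national culling-bag analysis), CV 0.84.
* ``r`` (per capita birth rate): gamma(shape 8.77, rate 2.76) cub fox^-1
  yr^-1, mean about 3.18 with sd about 1.07, from litter-size data.
* ``M`` (non-culling mortality): lognormal, median 0.34/26 per step (annual
  0.34 from a maximum-age meta-analysis), CV 0.58.
* ``d`` (rate of successful search): lognormal, median 2.01 km^2 hr^-1,
  CV 0.56, from a mechanistic model of the lamping search process.
* ``K``: uniform(0.001, 13.9) fox km^-2 — the upper bound is a healthy urban
  fox density, a ceiling for what a rural population could reach.
* ``N0``: uniform(0.001, K) — any value up to carrying capacity but not
  higher, since the culling history before the series start is unknown.

Lognormal CVs are the distribution's coefficient of variation, so
``sigma^2 = ln(1 + CV^2)``. The vague mode (used for simulation-estimation
comparisons) replaces the informative v, r, M, d with wide uniforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import DENSITY_FLOOR, PARAM_NAMES, ModelParams
from .schedules import RecruitmentSchedule

__all__ = [
    "ParamPrior",
    "PriorSet",
    "build_priors",
    "annual_to_step",
    "lognormal_from_median_cv",
    "prior_summaries",
    "post_model_pre_data",
]

STEPS_PER_YEAR = 26


def annual_to_step(rate_annual: float, steps: int = 26) -> float:
    """Convert an annual rate to a per-step rate by dividing by the step count.

    ``steps=26`` gives the two-weekly model scale, ``steps=52`` the weekly
    reporting scale.
    """
    if rate_annual < 0:
        raise ValueError("rate must be nonnegative")
    if steps not in (26, 52):
        raise ValueError("steps must be 26 (two-weekly) or 52 (weekly)")
    return rate_annual / steps


def lognormal_from_median_cv(median: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and coefficient of variation."""
    if median <= 0 or cv <= 0:
        raise ValueError("median and CV must be positive")
    return math.log(median), math.sqrt(math.log1p(cv**2))


@dataclass(frozen=True)
class ParamPrior:
    """One marginal prior: kind in {uniform, lognormal, gamma}.

    ``a, b`` are (lower, upper) for uniform, (mu, sigma) for lognormal, and
    (shape, rate) for gamma.
    """

    kind: str
    a: float
    b: float

    def dist(self):
        if self.kind == "uniform":
            return stats.uniform(self.a, self.b - self.a)
        if self.kind == "lognormal":
            return stats.lognorm(s=self.b, scale=math.exp(self.a))
        if self.kind == "gamma":
            return stats.gamma(self.a, scale=1.0 / self.b)
        raise ValueError(f"unknown prior kind {self.kind!r}")

    def logpdf(self, x: float) -> float:
        return float(self.dist().logpdf(x))

    def sample(self, rng: np.random.Generator, size=None):
        return self.dist().rvs(size=size, random_state=rng)


# Vague-mode uniform upper bounds: generous multiples of the informative prior
# medians (documented as a re-specification, not the original study's exact
# vague bounds, which are not printed).
VAGUE_UPPERS = {"v": 1.0, "r": 6.0, "M": 0.1, "d": 10.0}

_M_VARIANTS = {
    # alternative meta-analytic mortality prior from body mass (intrinsic only)
    "max_age": (0.34 / 26.0, 0.58),
    "body_mass": (0.27 / 26.0, 0.60),
}


@dataclass(frozen=True)
class PriorSet:
    """Joint prior over (N0, K, v, r, M, d) with N0 <= K enforced jointly."""

    K: ParamPrior
    N0_upper: float  # N0 ~ uniform(0.001, min(N0_upper, K))
    v: ParamPrior
    r: ParamPrior
    M: ParamPrior
    d: ParamPrior
    mode: str = "informative"
    sigma_p: float = 0.2

    def marginal(self, name: str) -> ParamPrior:
        if name == "N0":
            return ParamPrior("uniform", DENSITY_FLOOR, self.N0_upper)
        return getattr(self, name)

    def sample_params(self, rng: np.random.Generator) -> ModelParams:
        """One joint draw; N0 is drawn uniform below the drawn K."""
        K = float(self.K.sample(rng))
        n0_hi = min(self.N0_upper, K)
        N0 = float(rng.uniform(DENSITY_FLOOR, n0_hi))
        return ModelParams(
            N0=N0,
            K=K,
            v=float(self.v.sample(rng)),
            r=float(self.r.sample(rng)),
            M=float(self.M.sample(rng)),
            d=float(self.d.sample(rng)),
            sigma_p=self.sigma_p,
        )

    def log_density(self, p: ModelParams) -> float:
        """Joint log prior density at a parameter point."""
        n0_hi = min(self.N0_upper, p.K)
        if not DENSITY_FLOOR <= p.N0 <= n0_hi:
            return -np.inf
        lp = -math.log(n0_hi - DENSITY_FLOOR)
        for name in ("K", "v", "r", "M", "d"):
            lp += getattr(self, name).logpdf(getattr(p, name))
        return lp


_OVERRIDE_KEYS = {
    "priors.K.upper",
    "priors.N0.upper",
    "priors.M.variant",
    "priors.r.variant",
}


def build_priors(mode: str = "informative", overrides: dict | None = None) -> PriorSet:
    """Construct the prior set, optionally applying sensitivity overrides.

    Overrides (the documented sensitivity variants):
    ``priors.K.upper`` (e.g. 25.8), ``priors.N0.upper`` (e.g. 6.95),
    ``priors.M.variant`` in {max_age, body_mass}, ``priors.r.variant`` in
    {gamma, uniform} (uniform: vague U(0, 6)).
    """
    if mode not in ("informative", "vague"):
        raise ValueError(f"mode must be 'informative' or 'vague', got {mode!r}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ValueError(f"unknown prior override keys: {sorted(unknown)}")

    K_upper = float(overrides.get("priors.K.upper", 13.9))
    N0_upper = float(overrides.get("priors.N0.upper", K_upper))

    if mode == "vague":
        v = ParamPrior("uniform", 0.0, VAGUE_UPPERS["v"])
        r = ParamPrior("uniform", 0.0, VAGUE_UPPERS["r"])
        M = ParamPrior("uniform", 0.0, VAGUE_UPPERS["M"])
        d = ParamPrior("uniform", 0.0, VAGUE_UPPERS["d"])
    else:
        v = ParamPrior("lognormal", *lognormal_from_median_cv(2.41 / 26.0, 0.84))
        m_variant = overrides.get("priors.M.variant", "max_age")
        if m_variant not in _M_VARIANTS:
            raise ValueError(f"unknown M variant {m_variant!r}")
        M = ParamPrior("lognormal", *lognormal_from_median_cv(*_M_VARIANTS[m_variant]))
        r_variant = overrides.get("priors.r.variant", "gamma")
        if r_variant == "gamma":
            r = ParamPrior("gamma", 8.77, 2.76)
        elif r_variant == "uniform":
            r = ParamPrior("uniform", 0.0, 6.0)
        else:
            raise ValueError(f"unknown r variant {r_variant!r}")
        d = ParamPrior("lognormal", *lognormal_from_median_cv(2.01, 0.56))

    return PriorSet(
        K=ParamPrior("uniform", DENSITY_FLOOR, K_upper),
        N0_upper=N0_upper,
        v=v,
        r=r,
        M=M,
        d=d,
        mode=mode,
    )


def prior_summaries(ps: PriorSet) -> "pandas.DataFrame":
    """Closed-form median/mean/sd/CV per parameter (no sampling).

    The N0 row summarizes the marginal uniform(0.001, N0_upper) bound, not
    the joint (N0 | K) distribution.
    """
    import pandas as pd

    rows = []
    for name in PARAM_NAMES:
        dist = ps.marginal(name).dist()
        mean, sd = float(dist.mean()), float(dist.std())
        rows.append(
            {
                "parameter": name,
                "median": float(dist.median()),
                "mean": mean,
                "sd": sd,
                "cv": sd / mean if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def post_model_pre_data(
    series,
    ps: PriorSet,
    sched: RecruitmentSchedule,
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Final-step density draws under the priors pushed through the model.

    Joint-prior parameter draws are forward-simulated through the state
    equations conditioned on the cull inputs, with fresh process errors and
    no likelihood weighting. Comparing this distribution with the posterior
    at the same step shows how much the detection data updated the model.
    """
    from .model_core import forward_simulate
    from .schedules import redistribute_cub_cull

    rng = np.random.default_rng(seed)
    C = redistribute_cub_cull(series.C_obs, sched, series.years, series.steps)
    w = sched.w[series.steps - 1]
    out = np.empty(n_draws)
    for i in range(n_draws):
        params = ps.sample_params(rng)
        eps = rng.normal(0.0, params.sigma_p, size=len(series))
        traj = forward_simulate(params, series.L, series.S, C, w, eps)
        out[i] = traj.N[-1]
    return out
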