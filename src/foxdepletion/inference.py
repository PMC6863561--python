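"""MCMC fitting, convergence diagnostics and posterior summaries.

The model is fitted on the proportion-of-carrying-capacity scale (P_t =
N_t/K), which weakens the posterior correlation between the latent states
and K and mixes far better than the natural scale. Densities are recovered
afterwards as N_t = P_t * K. The sampler is an adaptive random-walk
Metropolis-within-Gibbs (see :mod:`foxdepletion._sampler`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _sampler
from .model_core import DENSITY_FLOOR, PARAM_NAMES, EstateSeries, forward_simulate
from .priors import ParamPrior, PriorSet
from .schedules import RecruitmentSchedule, redistribute_cub_cull

__all__ = [
    "MCMCConfig",
    "PosteriorSample",
    "ConvergenceWarning",
    "fit",
    "gelman_rubin",
    "summarize",
    "reconstruct_density",
    "empirical_process_sd",
    "annualize_step_rate",
]

RHAT_THRESHOLD = 1.01


class ConvergenceWarning(UserWarning):
    """Emitted when a fit's worst split R-hat exceeds the configured threshold."""


#: (burn_in, thin, n_recorded) presets. ``full`` mirrors the reference
#: protocol (100k burn-in, 1-in-100 thinning, 10k recorded per chain);
#: ``standard`` and ``reduced`` are desk-scale settings for synthetic series.
PROFILES = {
    "full": (150_000, 100, 10_000),
    "standard": (30_000, 30, 1_500),
    "reduced": (10_000, 10, 1_000),
}


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 2
    burn_in: int = 100_000
    thin: int = 100
    n_recorded: int = 10_000
    seed: int = 0
    backend: str = "builtin-MH"

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.thin, self.n_recorded) <= 0:
            raise ValueError("all MCMC settings must be positive")
        if self.backend != "builtin-MH":
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def profile(cls, name: str, seed: int = 0, n_chains: int = 2) -> "MCMCConfig":
        burn, thin, rec = PROFILES[name]
        return cls(n_chains=n_chains, burn_in=burn, thin=thin, n_recorded=rec, seed=seed)


@dataclass
class PosteriorSample:
    """Recorded draws: parameters on the natural scale, latent P_t, derived N_t.

    ``sigma_draws`` holds per-draw process-error s.d. values; it is constant
    at ``sigma_p`` unless the fit estimated sigma_p under a prior.
    """

    params: dict  # name -> (chains, draws)
    P: np.ndarray  # (chains, draws, T)
    sigma_p: float
    rhat: pd.Series  # per monitored quantity
    accept: np.ndarray  # (chains, 3)
    config: MCMCConfig
    sigma_draws: np.ndarray | None = None
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.converged = bool(self.rhat.max() < RHAT_THRESHOLD)

    @property
    def N(self) -> np.ndarray:
        """Density draws N_t = P_t * K, shape (chains, draws, T)."""
        return self.P * self.params["K"][:, :, None]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    @property
    def n_steps(self) -> int:
        return self.P.shape[2]


def _encode_priors(ps: PriorSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = {"uniform": _sampler.UNIFORM, "lognormal": _sampler.LOGNORMAL,
             "gamma": _sampler.GAMMA}
    kinds = np.zeros(6, dtype=np.int64)
    pa = np.zeros(6)
    pb = np.zeros(6)
    # N0 slot: only the upper bound is used (joint uniform below K)
    pa[0], pb[0] = DENSITY_FLOOR, ps.N0_upper
    for i, name in enumerate(PARAM_NAMES[1:], start=1):
        pr: ParamPrior = getattr(ps, name)
        kinds[i] = codes[pr.kind]
        pa[i], pb[i] = pr.a, pr.b
    return kinds, pa, pb


def fit(
    series: EstateSeries,
    ps: PriorSet,
    sched: RecruitmentSchedule,
    cfg: MCMCConfig,
    check_requirements: bool = True,
    v_multiplier: np.ndarray | None = None,
    sigma_prior: ParamPrior | None = None,
) -> PosteriorSample:
    """Sample the joint posterior of parameters and latent states.

    Latent chains are initialized by a deterministic forward pass from an
    independent joint-prior draw, which is always feasible under the density
    floor. Non-convergence (any split R-hat above 1.01) raises a
    :class:`ConvergenceWarning`, never a silent success.

    ``v_multiplier`` optionally scales immigration per step (the seasonal
    immigration variant); ``sigma_prior`` makes sigma_p an estimated
    parameter (uniform or lognormal prior) instead of fixed at
    ``ps.sigma_p``.
    """
    if check_requirements:
        from .synthetic_data import check_data_requirements

        report = check_data_requirements(series, sched)
        if not report.passed:
            raise ValueError(
                "series fails the data-requirement screen "
                f"({'; '.join(report.reasons)}); pass check_requirements=False "
                "to fit anyway"
            )

    C = redistribute_cub_cull(series.C_obs, sched, series.years, series.steps)
    w = sched.w[series.steps - 1]
    kinds, pa, pb = _encode_priors(ps)
    T = len(series)
    E = series.E.astype(float)
    Yf = series.Y.astype(float)
    vmult = (np.ones(T) if v_multiplier is None
             else np.asarray(v_multiplier, dtype=float))
    if vmult.shape != (T,):
        raise ValueError("v_multiplier must be aligned with the series")
    if sigma_prior is None:
        sig_kind, sig_a, sig_b = _sampler.FIXED, 0.0, 1.0
    else:
        sig_codes = {"uniform": _sampler.UNIFORM, "lognormal": _sampler.LOGNORMAL}
        if sigma_prior.kind not in sig_codes:
            raise ValueError("sigma_prior must be uniform or lognormal")
        sig_kind = sig_codes[sigma_prior.kind]
        sig_a, sig_b = sigma_prior.a, sigma_prior.b

    n_iter = cfg.thin * cfg.n_recorded
    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
                   ss.spawn(cfg.n_chains)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    theta_chains = np.empty((cfg.n_chains, cfg.n_recorded, 6))
    x_chains = np.empty((cfg.n_chains, cfg.n_recorded, T))
    sigma_chains = np.empty((cfg.n_chains, cfg.n_recorded))
    accept = np.empty((cfg.n_chains, 3))
    for c in range(cfg.n_chains):
        theta0, x0 = _init_chain(series, ps, C, w, vmult, rng, kinds, pa, pb)
        th, x, sig, acc = _sampler.run_chain(
            E, Yf, series.L, series.S, C, w, vmult,
            ps.sigma_p, sig_kind, sig_a, sig_b,
            kinds, pa, pb, theta0, x0,
            cfg.burn_in, n_iter, cfg.thin, chain_seeds[c],
        )
        theta_chains[c], x_chains[c], sigma_chains[c], accept[c] = th, x, sig, acc

    params = {name: theta_chains[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    P = np.exp(x_chains)

    rhat_vals = {name: gelman_rubin(params[name]) for name in PARAM_NAMES}
    if sigma_prior is not None:
        rhat_vals["sigma_p"] = gelman_rubin(sigma_chains)
    for t in range(T):
        rhat_vals[f"P[{t}]"] = gelman_rubin(P[:, :, t])
    rhat = pd.Series(rhat_vals)

    post = PosteriorSample(
        params=params, P=P, sigma_p=ps.sigma_p, rhat=rhat,
        accept=accept, config=cfg,
        sigma_draws=sigma_chains if sigma_prior is not None else None,
    )
    if not post.converged:
        worst = rhat.idxmax()
        warnings.warn(
            f"chains may not have converged: max split R-hat = "
            f"{rhat.max():.4f} ({worst})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return post


def _init_chain(series, ps, C, w, vmult, rng, kinds, pa, pb, n_candidates=50):
    """Feasible, well-supported chain start.

    Forward-simulates candidate joint-prior draws (no process error) through
    the state equations conditioned on the culls and starts from the
    candidate with the highest joint log posterior. A single prior draw is a
    poor start on heavily culled series: most draws crash onto the density
    floor, a degenerate region of the posterior where the process model
    exerts no constraint, and chains seeded there can stay trapped.
    """
    T = len(series)
    E = series.E.astype(float)
    Yf = series.Y.astype(float)
    best_lp = -np.inf
    best = None
    for _ in range(n_candidates):
        cand = ps.sample_params(rng)
        traj = forward_simulate(cand, series.L, series.S, C, w, np.zeros(T))
        x0 = np.log(np.maximum(traj.N / cand.K, DENSITY_FLOOR / cand.K))
        theta0 = cand.as_array()
        lp = _sampler._full_lp(
            theta0, x0, np.exp(x0), ps.sigma_p, E, Yf,
            series.L, series.S, C, w, vmult,
        ) + _sampler._prior_lp(np.log(theta0), theta0, kinds, pa, pb)
        if lp > best_lp:
            best_lp = lp
            best = (theta0, x0)
    return best


def gelman_rubin(chains: np.ndarray) -> float:
    """Split Gelman-Rubin statistic (classic, non-rank-normalized) for one quantity.

    ``chains`` has shape (n_chains, n_draws). Routed through
    ``arviz.rhat(method="split")``; identical chains give exactly 1.
    """
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    if np.allclose(chains.var(axis=1), 0.0) or np.ptp(chains) == 0.0:
        # degenerate chains: between- and within-variance both collapse
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(chains, method="split"))


@dataclass
class PosteriorSummary:
    table: pd.DataFrame
    correlations: pd.DataFrame
    moderate_pairs: list

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}\n\nmoderate |rho| in 0.4-0.7: {self.moderate_pairs}"


def summarize(post: PosteriorSample) -> PosteriorSummary:
    """Posterior medians, CVs, 80/95% central intervals and parameter correlations.

    Pairs with moderate posterior correlation (|rho| between 0.4 and 0.7)
    are flagged in ``moderate_pairs``.
    """
    rows = []
    flat = {name: post.flat(name) for name in PARAM_NAMES}
    for name, x in flat.items():
        med = float(np.median(x))
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows.append({
            "parameter": name,
            "median": med,
            "cv": sd / mean if mean != 0 else np.nan,
            "q10": float(np.quantile(x, 0.10)),
            "q90": float(np.quantile(x, 0.90)),
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        })
    table = pd.DataFrame(rows).set_index("parameter")

    mat = np.column_stack([flat[n] for n in PARAM_NAMES])
    if mat.shape[0] > 1 and np.all(mat.std(axis=0) > 0):
        corr = np.corrcoef(mat, rowvar=False)
    else:
        corr = np.eye(6)
    correlations = pd.DataFrame(corr, index=PARAM_NAMES, columns=PARAM_NAMES)
    moderate = [
        (a, b, float(correlations.loc[a, b]))
        for i, a in enumerate(PARAM_NAMES)
        for b in PARAM_NAMES[i + 1:]
        if 0.4 <= abs(correlations.loc[a, b]) <= 0.7
    ]
    return PosteriorSummary(table=table, correlations=correlations,
                            moderate_pairs=moderate)


def reconstruct_density(
    post: PosteriorSample,
    quantiles: tuple = (0.10, 0.50, 0.90),
) -> pd.DataFrame:
    """Per-step quantiles of reconstructed density N_t = P_t * K."""
    N = post.N.reshape(-1, post.n_steps)
    qs = np.quantile(N, quantiles, axis=0)
    return pd.DataFrame(
        {f"q{int(round(q * 100))}": qs[i] for i, q in enumerate(quantiles)}
    )


def annualize_step_rate(rate_2wk: float, to: str = "weekly") -> float:
    """Convert a per-two-week rate to the weekly or annual reporting scale."""
    if to == "weekly":
        return rate_2wk / 2.0
    if to == "annual":
        return rate_2wk * 26.0
    raise ValueError("to must be 'weekly' or 'annual'")


def empirical_process_sd(
    post: PosteriorSample,
    series: EstateSeries,
    sched: RecruitmentSchedule,
) -> float:
    """Mean over draws of the s.d. of realized process errors.

    For each recorded draw the realized error at step t is the gap between
    the sampled log-state and the log of the deterministic balance predicted
    from the previous state (plus the sigma_p^2/2 bias correction). Values
    smaller than the assumed sigma_p indicate the fixed process error
    overstates the unmodelled variation.
    """
    C = redistribute_cub_cull(series.C_obs, sched, series.years, series.steps)
    w = sched.w[series.steps - 1]
    T = len(series)
    P = post.P.reshape(-1, T)
    K = post.flat("K")
    N0, v = post.flat("N0"), post.flat("v")
    r, M = post.flat("r"), post.flat("M")
    half = 0.5 * post.sigma_p**2

    eps = np.empty_like(P)
    eps[:, 0] = np.log(P[:, 0]) - (np.log(N0 / K) - half)
    Kc = K[:, None]
    G = w[:-1] * r[:, None] * P[:, :-1] * (1.0 - P[:, :-1]) - C[:-1] / Kc
    B = (
        P[:, :-1] * np.exp(-M)[:, None]
        + (v / K)[:, None] * (1.0 - P[:, :-1])
        + G
        - (series.L[:-1] + series.S[:-1]) / Kc
    )
    B = np.maximum(B, DENSITY_FLOOR / Kc)
    eps[:, 1:] = np.log(P[:, 1:]) - (np.log(B) - half)
    return float(np.mean(np.std(eps, axis=1, ddof=1)))
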