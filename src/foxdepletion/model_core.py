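"""State-process and observation kernels of the generalized depletion model.

The observable fox density ``N_t`` (fox km^-2, adults plus post-weaning cubs)
on a restricted culling area evolves on a two-weekly time-step, conditioned on
the recorded cull, as

    N_1 = N_0 * exp(eps_1 - sigma_p^2 / 2)
    N_t = [N_{t-1} e^{-M} + v (1 - N_{t-1}/K) + J_{t-1} - L_{t-1} - S_{t-1}]
          * exp(eps_t - sigma_p^2 / 2)
    J_t = w_t r N_t (1 - N_t/K) - C_t

with density-dependent immigration (rate ``v``) and weaned-cub recruitment
(per capita birth rate ``r`` scheduled by ``w_t``), instantaneous non-culling
mortality ``M``, lamping and other-method culls ``L_t``, ``S_t``, and the
redistributed cub cull ``C_t``. Lognormal process errors ``eps_t ~ N(0,
sigma_p)`` carry the -sigma_p^2/2 bias correction so the shock has mean one
(the equations track expected, not median, density). The bracketed balance is
floored at 0.001 fox km^-2 for numerical stability: conditioning on the
observed cull can otherwise drive predictions negative.

Detections are an effort-based index through a Holling disc with zero
handling time: ``E[Y_t] = d E_t N_t`` with ``Y_t ~ Poisson``, where ``d``
(km^2 hr^-1) is the rate of successful search and ``E_t`` the lamping hours.

For MCMC the model is reparameterized on the proportion-of-carrying-capacity
scale ``P_t = N_t / K`` (``G_t = J_t / K``), which decorrelates the latent
states from ``K``; both forms are provided and agree exactly up to the
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

DENSITY_FLOOR = 0.001  # fox km^-2

__all__ = [
    "DENSITY_FLOOR",
    "ModelParams",
    "EstateSeries",
    "StateTrajectory",
    "init_state",
    "step_density",
    "recruit",
    "step_proportion",
    "recruit_proportion",
    "expected_detections",
    "detection_loglik",
]


@dataclass(frozen=True)
class ModelParams:
    """The six estimated parameters plus the fixed process-error s.d.

    Units: ``N0``, ``K`` fox km^-2; ``v`` fox km^-2 per two-week step; ``r``
    cub fox^-1 yr^-1 (applied per step already scaled by ``w_t``, which sums
    to one over the year, so no /26 conversion applies to ``r``); ``M`` per
    two-week step; ``d`` km^2 hr^-1; ``sigma_p`` dimensionless.
    """

    N0: float
    K: float
    v: float
    r: float
    M: float
    d: float
    sigma_p: float = 0.2

    def __post_init__(self) -> None:
        for name in ("N0", "K", "v", "r", "M", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.N0, self.K, self.v, self.r, self.M, self.d])

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


PARAM_NAMES = ("N0", "K", "v", "r", "M", "d")


@dataclass
class EstateSeries:
    """Two-weekly culling-record series for one estate.

    ``E`` lamping hours, ``Y`` fox detections (counts), ``L``/``S``/``C_obs``
    lamping / other-method / cub-at-earth cull densities (fox km^-2),
    ``area`` km^2, and a calendar (``years``, ``steps``; step 1..26).
    """

    E: np.ndarray
    Y: np.ndarray
    L: np.ndarray
    S: np.ndarray
    C_obs: np.ndarray
    area: float
    years: np.ndarray
    steps: np.ndarray
    estate: str = ""

    def __post_init__(self) -> None:
        arrays = {
            "E": np.asarray(self.E, dtype=float),
            "L": np.asarray(self.L, dtype=float),
            "S": np.asarray(self.S, dtype=float),
            "C_obs": np.asarray(self.C_obs, dtype=float),
        }
        Y = np.asarray(self.Y)
        if not np.issubdtype(Y.dtype, np.integer):
            if np.any(Y != np.round(Y)):
                raise ValueError("detection counts Y must be integers")
            Y = Y.astype(np.int64)
        n = len(arrays["E"])
        years = np.asarray(self.years)
        steps = np.asarray(self.steps)
        lengths = {name: len(a) for name, a in arrays.items()}
        lengths.update(Y=len(Y), years=len(years), steps=len(steps))
        if len(set(lengths.values())) != 1:
            raise ValueError(f"series arrays have unequal lengths: {lengths}")
        for name, a in arrays.items():
            if np.any(a < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any(Y < 0):
            raise ValueError("Y must be nonnegative")
        if np.any(Y[arrays["E"] == 0] > 0):
            raise ValueError("detections recorded in steps with zero effort")
        if self.area <= 0:
            raise ValueError("estate area must be positive")
        self.E, self.L, self.S, self.C_obs = (
            arrays["E"], arrays["L"], arrays["S"], arrays["C_obs"],
        )
        self.Y, self.years, self.steps = Y, years, steps

    def __len__(self) -> int:
        return len(self.E)


@dataclass
class StateTrajectory:
    """Latent states of one realization: density, recruitment, process errors."""

    N: np.ndarray
    J: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.N) == len(self.J) == len(self.eps)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(self.N < DENSITY_FLOOR - 1e-12):
            raise ValueError(f"N must be >= {DENSITY_FLOOR} everywhere")


def init_state(params: ModelParams, eps1: float) -> float:
    """First-step density: N0 times the bias-corrected lognormal shock."""
    n1 = params.N0 * np.exp(eps1 - params.sigma_p**2 / 2.0)
    return max(n1, DENSITY_FLOOR)


def step_density(
    N_prev: float,
    J_prev: float,
    L_prev: float,
    S_prev: float,
    params: ModelParams,
    eps_t: float,
) -> float:
    """One transition on the natural density scale.

    The deterministic balance (survival + immigration + recruitment - cull)
    is floored at the density floor *after* the full balance, then multiplied
    by the process-error shock.
    """
    bracket = (
        N_prev * np.exp(-params.M)
        + params.v * (1.0 - N_prev / params.K)
        + J_prev
        - L_prev
        - S_prev
    )
    bracket = max(bracket, DENSITY_FLOOR)
    out = bracket * np.exp(eps_t - params.sigma_p**2 / 2.0)
    return max(out, DENSITY_FLOOR)


def recruit(N_t: float, C_t: float, w_t: float, params: ModelParams) -> float:
    """Weaned-cub recruitment J_t = w_t r N_t (1 - N_t/K) - C_t.

    May be negative when the redistributed cub cull exceeds the step's
    production; the negative value flows into the next transition's balance
    (the floor is applied only after the full balance), since the annual
    redistribution guarantees cub culls precede production only in aggregate.
    """
    return w_t * params.r * N_t * (1.0 - N_t / params.K) - C_t


def recruit_proportion(P_t: float, C_t: float, w_t: float, params: ModelParams) -> float:
    """Recruitment on the proportion scale: G_t = w_t r P_t (1 - P_t) - C_t/K."""
    return w_t * params.r * P_t * (1.0 - P_t) - C_t / params.K


def step_proportion(
    P_prev: float,
    G_prev: float,
    L_prev: float,
    S_prev: float,
    params: ModelParams,
    eps_t: float,
) -> float:
    """One transition on the P = N/K scale; floor at 0.001/K."""
    bracket = (
        P_prev * np.exp(-params.M)
        + params.v / params.K * (1.0 - P_prev)
        + G_prev
        - (L_prev + S_prev) / params.K
    )
    bracket = max(bracket, DENSITY_FLOOR / params.K)
    out = bracket * np.exp(eps_t - params.sigma_p**2 / 2.0)
    return max(out, DENSITY_FLOOR / params.K)


def expected_detections(d: float, E_t, N_t):
    """Expected detections d * E_t * N_t (Holling disc, zero handling time)."""
    d = float(d)
    if d < 0:
        raise ValueError("d must be nonnegative")
    E_t = np.asarray(E_t, dtype=float)
    N_t = np.asarray(N_t, dtype=float)
    if np.any(E_t < 0) or np.any(N_t < 0):
        raise ValueError("effort and density must be nonnegative")
    return d * E_t * N_t


def detection_loglik(Y, Yhat) -> float:
    """Poisson log-likelihood of detection counts given expectations.

    Steps with ``Yhat == 0`` contribute 0 when ``Y == 0`` (zero-effort steps)
    and -inf when ``Y > 0`` (returned, not raised: samplers treat it as an
    impossible state).
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if np.any(Yhat < 0):
        raise ValueError("expected detections must be nonnegative")
    if np.any(Y[Yhat == 0.0] > 0):
        return -np.inf
    pos = Yhat > 0.0
    y, lam = Y[pos], Yhat[pos]
    return float(np.sum(y * np.log(lam) - lam - gammaln(y + 1.0)))


def forward_simulate(
    params: ModelParams,
    L: np.ndarray,
    S: np.ndarray,
    C: np.ndarray,
    w: np.ndarray,
    eps: np.ndarray,
) -> StateTrajectory:
    """Propagate the state equations over a whole series.

    ``C`` is the redistributed cub cull and ``w`` the per-index schedule
    weight (both aligned with the series); ``eps`` the realized process
    errors. Returns densities, recruitment and the errors as a trajectory.
    """
    T = len(L)
    N = np.empty(T)
    J = np.empty(T)
    N[0] = init_state(params, eps[0])
    J[0] = recruit(N[0], C[0], w[0], params)
    for t in range(1, T):
        N[t] = step_density(N[t - 1], J[t - 1], L[t - 1], S[t - 1], params, eps[t])
        J[t] = recruit(N[t], C[t], w[t], params)
    return StateTrajectory(N=N, J=J, eps=np.asarray(eps, dtype=float))
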