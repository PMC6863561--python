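"""Adaptive Metropolis-within-Gibbs kernel for the reparameterized model.

The target is the joint posterior over the six parameters theta = (N0, K, v,
r, M, d), the latent log-states x_t = ln P_t (P_t = N_t / K), and (when a
prior is supplied for it) the process-error s.d. sigma_p:

    p(theta, x | Y) propto prior(theta)
        * N(x_1 | ln(N0/K) - sigma_p^2/2, sigma_p)
        * prod_t N(x_{t+1} | ln B_t - sigma_p^2/2, sigma_p)
        * prod_{E_t > 0} Poisson(Y_t | d E_t K P_t)

where B_t is the deterministic balance P_t e^{-M} + (m_t v/K)(1 - P_t) + G_t
- (L_t + S_t)/K floored at 0.001/K, G_t = w_t r P_t (1 - P_t) - C_t/K, and
m_t an optional per-step immigration multiplier (all ones in the reference
model; the seasonal-immigration variant zeroes April-July and rescales the
rest). Sampled states are likewise constrained to P_t >= 0.001/K.

Parameters are updated one-at-a-time by random-walk proposals on the log
scale (step sizes tuned to ~44% acceptance during burn-in), plus one joint
adaptive-Metropolis block move per sweep using the running empirical
covariance of log-theta; latent states are updated one-site-at-a-time, which
emulates the one-site Gibbs updating of the BUGS samplers this model family
was originally fitted with. All adaptation is frozen at the end of burn-in.

Everything here is numba-compiled; the public interface is
:func:`run_chain`, consumed by :mod:`foxdepletion.inference`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# prior kind codes
UNIFORM = 0
LOGNORMAL = 1
GAMMA = 2
FIXED = -1  # sigma_p not sampled

FLOOR = 0.001  # density floor, fox km^-2


@njit(cache=True)
def _prior_lp(y, theta, kinds, pa, pb):
    """Joint log prior density of theta plus the log-scale Jacobian sum(y).

    Index 0 (N0) is uniform(FLOOR, min(pb[0], K)) — the joint N0 <= K
    constraint lives here.
    """
    K = theta[1]
    lp = 0.0
    for i in range(6):
        th = theta[i]
        if i == 0:
            hi = pb[0] if pb[0] < K else K
            if th < FLOOR or th > hi or hi <= FLOOR:
                return -np.inf
            lp += -math.log(hi - FLOOR) + y[i]
        elif kinds[i] == UNIFORM:
            if th < pa[i] or th > pb[i]:
                return -np.inf
            lp += -math.log(pb[i] - pa[i]) + y[i]
        elif kinds[i] == LOGNORMAL:
            z = (y[i] - pa[i]) / pb[i]
            lp += -0.5 * z * z - math.log(pb[i])
        else:  # GAMMA(shape=pa, rate=pb)
            a, b = pa[i], pb[i]
            lp += a * math.log(b) - math.lgamma(a) + a * y[i] - b * th
    return lp


@njit(cache=True)
def _sigma_prior_lp(sigma, kind, a, b):
    """Log prior of sigma_p plus log-scale Jacobian; 0 when fixed."""
    if kind == FIXED:
        return 0.0
    ls = math.log(sigma)
    if kind == UNIFORM:
        if sigma < a or sigma > b:
            return -np.inf
        return -math.log(b - a) + ls
    # lognormal(mu=a, s=b)
    z = (ls - a) / b
    return -0.5 * z * z - math.log(b)


@njit(cache=True, inline="always")
def _bracket(P, t, K, v, r, M, L, S, C, w, vmult):
    G = w[t] * r * P * (1.0 - P) - C[t] / K
    B = P * math.exp(-M) + vmult[t] * v / K * (1.0 - P) + G - (L[t] + S[t]) / K
    fl = FLOOR / K
    return B if B > fl else fl


@njit(cache=True)
def _full_lp(theta, x, P, sigma, E, Y, L, S, C, w, vmult):
    """Full log target (up to theta- and sigma-free constants)."""
    T = x.shape[0]
    N0, K, v, r, M, d = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    lp = 0.0
    lfl = math.log(FLOOR / K)
    for t in range(T):
        if x[t] < lfl:
            return -np.inf
    half = 0.5 * sigma * sigma
    lsig = math.log(sigma)
    mean = math.log(N0 / K) - half
    z = (x[0] - mean) / sigma
    lp += -0.5 * z * z - lsig
    for t in range(T - 1):
        B = _bracket(P[t], t, K, v, r, M, L, S, C, w, vmult)
        mean = math.log(B) - half
        z = (x[t + 1] - mean) / sigma
        lp += -0.5 * z * z - lsig
    ldEK = math.log(d * K)
    for t in range(T):
        if E[t] > 0.0:
            lam = d * E[t] * K * P[t]
            lp += Y[t] * (ldEK + math.log(E[t]) + x[t]) - lam
    return lp


@njit(cache=True)
def run_chain(
    E, Y, L, S, C, w, vmult,
    sigma0, sig_kind, sig_a, sig_b,
    kinds, pa, pb,
    theta0, x0,
    n_burn, n_iter, thin,
    seed,
):
    """One MCMC chain; returns recorded draws and acceptance rates.

    Returns
    -------
    theta_out : (n_rec, 6) parameter draws on the natural scale
    x_out : (n_rec, T) latent log-proportion draws
    sigma_out : (n_rec,) process-error s.d. draws (constant when fixed)
    acc : (3,) mean acceptance rates (param single-site, param block, latents)
    """
    np.random.seed(seed)
    T = x0.shape[0]
    x = x0.copy()
    P = np.exp(x)
    y = np.log(theta0)
    theta = theta0.copy()
    sigma = sigma0

    n_rec = n_iter // thin
    theta_out = np.empty((n_rec, 6))
    x_out = np.empty((n_rec, T))
    sigma_out = np.empty(n_rec)

    lp = (
        _full_lp(theta, x, P, sigma, E, Y, L, S, C, w, vmult)
        + _prior_lp(y, theta, kinds, pa, pb)
        + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
    )

    # adaptation state
    ls_par = np.full(6, math.log(0.1))
    ls_lat = np.full(T, math.log(0.2))
    ls_sig = math.log(0.1)
    ls_scl = math.log(0.3)
    ls_scd = math.log(0.3)
    ls_seg = math.log(0.3)
    ls_win = math.log(0.3)
    ls_blk = 0.0
    mu = y.copy()
    cov = np.eye(6) * 1e-4
    chol = np.linalg.cholesky(cov + np.eye(6) * 1e-9)
    n_adapt = 0

    acc_site = 0.0
    acc_blk = 0.0
    acc_lat = 0.0
    n_site = 0
    n_blk = 0
    n_lat = 0

    total = n_burn + n_iter
    for it in range(total):
        adapting = it < n_burn
        gamma = 1.0 / (1.0 + 0.1 * (it + 1.0)) ** 0.6 if adapting else 0.0

        # --- single-site parameter updates (full recompute) ---
        for i in range(6):
            y_prop = y.copy()
            y_prop[i] = y[i] + math.exp(ls_par[i]) * np.random.normal()
            th_prop = np.exp(y_prop)
            plp = _prior_lp(y_prop, th_prop, kinds, pa, pb)
            if plp > -np.inf:
                lp_prop = (
                    plp
                    + _full_lp(th_prop, x, P, sigma, E, Y, L, S, C, w, vmult)
                    + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
                )
            else:
                lp_prop = -np.inf
            a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
            if np.random.random() < a:
                y = y_prop
                theta = th_prop
                lp = lp_prop
            if adapting:
                ls_par[i] += gamma * (a - 0.44)
            else:
                acc_site += a
                n_site += 1

        # --- sigma_p update (only when a prior is supplied) ---
        if sig_kind != FIXED:
            sig_prop = sigma * math.exp(math.exp(ls_sig) * np.random.normal())
            slp = _sigma_prior_lp(sig_prop, sig_kind, sig_a, sig_b)
            if slp > -np.inf:
                lp_prop = (
                    slp
                    + _prior_lp(y, theta, kinds, pa, pb)
                    + _full_lp(theta, x, P, sig_prop, E, Y, L, S, C, w, vmult)
                )
            else:
                lp_prop = -np.inf
            a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
            if np.random.random() < a:
                sigma = sig_prop
                lp = lp_prop
            if adapting:
                ls_sig += gamma * (a - 0.44)

        # --- joint adaptive-Metropolis block on all six parameters ---
        z6 = np.empty(6)
        for i in range(6):
            z6[i] = np.random.normal()
        step = chol @ z6
        y_prop = y + math.exp(ls_blk) * step
        th_prop = np.exp(y_prop)
        plp = _prior_lp(y_prop, th_prop, kinds, pa, pb)
        if plp > -np.inf:
            lp_prop = (
                plp
                + _full_lp(th_prop, x, P, sigma, E, Y, L, S, C, w, vmult)
                + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
            )
        else:
            lp_prop = -np.inf
        a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
        if np.random.random() < a:
            y = y_prop
            theta = th_prop
            lp = lp_prop
        if adapting:
            ls_blk += gamma * (a - 0.25)
            n_adapt += 1
            dy = y - mu
            mu = mu + gamma * dy
            cov = cov + gamma * (np.outer(dy, dy) - cov)
            if n_adapt % 100 == 0:
                chol = np.linalg.cholesky(
                    cov * (2.38 * 2.38 / 6.0) + np.eye(6) * 1e-9
                )
        else:
            acc_blk += a
            n_blk += 1

        # --- density-invariant K scaling move ---
        # Proposes K' = cK while shifting every latent log-state by -ln c, so
        # the density trajectory N_t = K P_t (and the Poisson means d E_t N_t)
        # are unchanged; K then mixes through the dynamics and its prior
        # rather than by slow diffusion against the states. The map is a
        # shear in (ln K, x) coordinates (unit Jacobian), so the plain
        # Metropolis ratio applies.
        lc = math.exp(ls_scl) * np.random.normal()
        y_prop = y.copy()
        y_prop[0] = y[0] + lc  # N0 co-scales so N0/K (first transition) is invariant
        y_prop[1] = y[1] + lc
        th_prop = np.exp(y_prop)
        x_prop = x - lc
        P_prop = np.exp(x_prop)
        plp = _prior_lp(y_prop, th_prop, kinds, pa, pb)
        if plp > -np.inf:
            lp_prop = (
                plp
                + _full_lp(th_prop, x_prop, P_prop, sigma, E, Y, L, S, C, w, vmult)
                + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
            )
        else:
            lp_prop = -np.inf
        a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
        if np.random.random() < a:
            y = y_prop
            theta = th_prop
            x = x_prop
            P = P_prop
            lp = lp_prop
        if adapting:
            ls_scl += gamma * (a - 0.44)

        # --- detection-invariant d scaling move ---
        # d' = c d with every latent shifted by -ln c keeps the Poisson means
        # d E_t K P_t fixed while sliding the whole density trajectory up or
        # down: this is the stiff d-vs-density direction of the posterior.
        # Again a shear with unit Jacobian and symmetric ln c proposal.
        lc = math.exp(ls_scd) * np.random.normal()
        y_prop = y.copy()
        y_prop[5] = y[5] + lc
        th_prop = np.exp(y_prop)
        x_prop = x - lc
        P_prop = np.exp(x_prop)
        plp = _prior_lp(y_prop, th_prop, kinds, pa, pb)
        if plp > -np.inf:
            lp_prop = (
                plp
                + _full_lp(th_prop, x_prop, P_prop, sigma, E, Y, L, S, C, w, vmult)
                + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
            )
        else:
            lp_prop = -np.inf
        a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
        if np.random.random() < a:
            y = y_prop
            theta = th_prop
            x = x_prop
            P = P_prop
            lp = lp_prop
        if adapting:
            ls_scd += gamma * (a - 0.44)

        # --- leading-segment level shift ---
        # Shifts ln N0 and the latent states x_0..x_cut (random cutpoint) by
        # a common amount: the level of the early, data-poor part of the
        # trajectory is a stiff, weakly identified direction that single-site
        # updates traverse only diffusively. Symmetric proposal, unit
        # Jacobian (translation), so plain Metropolis again.
        lc = math.exp(ls_seg) * np.random.normal()
        tcut = np.random.randint(0, T)
        y_prop = y.copy()
        y_prop[0] = y[0] + lc
        th_prop = np.exp(y_prop)
        x_prop = x.copy()
        for t in range(tcut + 1):
            x_prop[t] = x[t] + lc
        P_prop = np.exp(x_prop)
        plp = _prior_lp(y_prop, th_prop, kinds, pa, pb)
        if plp > -np.inf:
            lp_prop = (
                plp
                + _full_lp(th_prop, x_prop, P_prop, sigma, E, Y, L, S, C, w, vmult)
                + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
            )
        else:
            lp_prop = -np.inf
        a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
        if np.random.random() < a:
            y = y_prop
            theta = th_prop
            x = x_prop
            P = P_prop
            lp = lp_prop
        if adapting:
            ls_seg += gamma * (a - 0.30)

        # --- interior-window level shift ---
        # Shifts a random contiguous block of latent states by a common
        # amount; complements the leading-segment move for trough/peak
        # excursions in the middle of the series whose overall level is the
        # slow direction. Translation proposal: symmetric, unit Jacobian.
        lc = math.exp(ls_win) * np.random.normal()
        t1 = np.random.randint(0, T)
        t2 = t1 + np.random.randint(0, T - t1)
        x_prop = x.copy()
        for t in range(t1, t2 + 1):
            x_prop[t] = x[t] + lc
        P_prop = np.exp(x_prop)
        lp_prop = (
            _prior_lp(y, theta, kinds, pa, pb)
            + _full_lp(theta, x_prop, P_prop, sigma, E, Y, L, S, C, w, vmult)
            + _sigma_prior_lp(sigma, sig_kind, sig_a, sig_b)
        )
        a = 1.0 if lp_prop - lp > 0.0 else math.exp(lp_prop - lp)
        if np.random.random() < a:
            x = x_prop
            P = P_prop
            lp = lp_prop
        if adapting:
            ls_win += gamma * (a - 0.30)

        # --- single-site latent updates ---
        N0, K, v, r, M, d = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
        half = 0.5 * sigma * sigma
        lfl = math.log(FLOOR / K)
        for t in range(T):
            xp = x[t] + math.exp(ls_lat[t]) * np.random.normal()
            if xp < lfl:
                a = 0.0
            else:
                Pp = math.exp(xp)
                # incoming transition
                if t == 0:
                    mean = math.log(N0 / K) - half
                else:
                    B = _bracket(P[t - 1], t - 1, K, v, r, M, L, S, C, w, vmult)
                    mean = math.log(B) - half
                z_old = (x[t] - mean) / sigma
                z_new = (xp - mean) / sigma
                dlp = 0.5 * (z_old * z_old - z_new * z_new)
                # outgoing transition
                if t < T - 1:
                    B_old = _bracket(P[t], t, K, v, r, M, L, S, C, w, vmult)
                    B_new = _bracket(Pp, t, K, v, r, M, L, S, C, w, vmult)
                    mo = math.log(B_old) - half
                    mn = math.log(B_new) - half
                    zo = (x[t + 1] - mo) / sigma
                    zn = (x[t + 1] - mn) / sigma
                    dlp += 0.5 * (zo * zo - zn * zn)
                # observation
                if E[t] > 0.0:
                    dlp += Y[t] * (xp - x[t]) - d * E[t] * K * (Pp - P[t])
                a = 1.0 if dlp > 0.0 else math.exp(dlp)
                if np.random.random() < a:
                    x[t] = xp
                    P[t] = Pp
                    lp += dlp
            if adapting:
                ls_lat[t] += gamma * (a - 0.44)
            else:
                acc_lat += a
                n_lat += 1

        if not adapting:
            k = it - n_burn
            if (k + 1) % thin == 0:
                j = k // thin
                theta_out[j] = theta
                x_out[j] = x
                sigma_out[j] = sigma

    acc = np.empty(3)
    acc[0] = acc_site / max(n_site, 1)
    acc[1] = acc_blk / max(n_blk, 1)
    acc[2] = acc_lat / max(n_lat, 1)
    return theta_out, x_out, sigma_out, acc
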