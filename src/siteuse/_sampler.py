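"""Numba kernels for posterior sampling of the seasonal site-use model.

One Gibbs sweep consists of
  1. an exact joint draw of each site-year's latent daily occupancy chain
     by forward filtering / backward sampling (FFBS),
  2. conjugate Beta draws of the day-1 occupancy probabilities,
  3. adaptive random-walk Metropolis updates of the probit quadratic
     coefficients, the site/year random effects and the detection
     coefficients,
  4. conjugate Gamma draws of the random-effect precisions.

Persistence terms of the process likelihood involve only transitions out of
occupied days and colonization terms only transitions out of empty days, so
the two blocks are evaluated separately.  Step sizes adapt towards a 0.44
acceptance rate during burn-in and are frozen afterwards.  All randomness
comes from numba's global RNG, seeded once per chain, which makes chains
bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT1_2 = 0.7071067811865476
_PCLIP = 1e-12
_NEG_BIG = -1e30


@njit(cache=True, inline="always")
def _probit_cdf(x):
    p = 0.5 * math.erfc(-x * _SQRT1_2)
    if p < _PCLIP:
        p = _PCLIP
    elif p > 1.0 - _PCLIP:
        p = 1.0 - _PCLIP
    return p


@njit(cache=True, inline="always")
def _logaddexp(a, b):
    if a < b:
        a, b = b, a
    if a <= _NEG_BIG:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def _cell_logb(y, sll, t, i, delta, logb0, logb1):
    """Observation log-likelihood per day for both latent states (one cell)."""
    J, D = y.shape[0], y.shape[1]
    for d in range(D):
        b0 = 0.0
        b1 = 0.0
        for j in range(J):
            yv = y[j, d, t, i]
            if yv < 0:
                break
            p = sll[j, d, t, i] / (sll[j, d, t, i] + delta)
            if p < _PCLIP:
                p = _PCLIP
            elif p > 1.0 - _PCLIP:
                p = 1.0 - _PCLIP
            if yv == 1:
                b0 = _NEG_BIG
                b1 += math.log(p)
            else:
                b1 += math.log(1.0 - p)
        logb0[d] = b0
        logb1[d] = b1


@njit(cache=True)
def _cell_rates(coef, eps_site_i, eps_year_t, jday, out):
    """Daily probit rates for one cell; out[d] governs day d+1 -> d+2."""
    for d in range(len(jday) - 1):
        x = (coef[0] + coef[1] * jday[d] + coef[2] * jday[d] * jday[d]
             + eps_site_i + eps_year_t)
        out[d] = _probit_cdf(x)


@njit(cache=True)
def _ffbs_cell(logb0, logb1, phi, gam, psi1, u_out, a0, a1):
    """Joint draw of one site-year latent chain given rates and data."""
    D = len(logb0)
    p1 = psi1
    if p1 < _PCLIP:
        p1 = _PCLIP
    elif p1 > 1.0 - _PCLIP:
        p1 = 1.0 - _PCLIP
    a0[0] = math.log(1.0 - p1) + logb0[0]
    a1[0] = math.log(p1) + logb1[0]
    for d in range(1, D):
        ph = phi[d - 1]
        ga = gam[d - 1]
        n0 = _logaddexp(a0[d - 1] + math.log(1.0 - ga),
                        a1[d - 1] + math.log(1.0 - ph)) + logb0[d]
        n1 = _logaddexp(a0[d - 1] + math.log(ga),
                        a1[d - 1] + math.log(ph)) + logb1[d]
        m = n0 if n0 > n1 else n1
        a0[d] = n0 - m
        a1[d] = n1 - m
    # backward sampling
    pr1 = 1.0 / (1.0 + math.exp(a0[D - 1] - a1[D - 1]))
    u_out[D - 1] = 1 if np.random.random() < pr1 else 0
    for d in range(D - 2, -1, -1):
        ph = phi[d]
        ga = gam[d]
        if u_out[d + 1] == 1:
            w1 = a1[d] + math.log(ph)
            w0 = a0[d] + math.log(ga)
        else:
            w1 = a1[d] + math.log(1.0 - ph)
            w0 = a0[d] + math.log(1.0 - ga)
        pr1 = 1.0 / (1.0 + math.exp(w0 - w1))
        u_out[d] = 1 if np.random.random() < pr1 else 0


@njit(cache=True)
def _pers_ll(u, jday, c0, c1, c2, eps_site, eps_year, i_sel, t_sel):
    """Process log-likelihood terms for transitions out of occupied days."""
    D, T, I = u.shape
    s = 0.0
    for t in range(T):
        if t_sel >= 0 and t != t_sel:
            continue
        for i in range(I):
            if i_sel >= 0 and i != i_sel:
                continue
            off = eps_site[i] + eps_year[t]
            for d in range(1, D):
                if u[d - 1, t, i] == 1:
                    x = (c0 + c1 * jday[d - 1] + c2 * jday[d - 1] * jday[d - 1]
                         + off)
                    p = _probit_cdf(x)
                    if u[d, t, i] == 1:
                        s += math.log(p)
                    else:
                        s += math.log(1.0 - p)
    return s


@njit(cache=True)
def _col_ll(u, jday, c0, c1, c2, eps_site, eps_year, i_sel, t_sel):
    """Process log-likelihood terms for transitions out of empty days."""
    D, T, I = u.shape
    s = 0.0
    for t in range(T):
        if t_sel >= 0 and t != t_sel:
            continue
        for i in range(I):
            if i_sel >= 0 and i != i_sel:
                continue
            off = eps_site[i] + eps_year[t]
            for d in range(1, D):
                if u[d - 1, t, i] == 0:
                    x = (c0 + c1 * jday[d - 1] + c2 * jday[d - 1] * jday[d - 1]
                         + off)
                    p = _probit_cdf(x)
                    if u[d, t, i] == 1:
                        s += math.log(p)
                    else:
                        s += math.log(1.0 - p)
    return s


@njit(cache=True)
def _det_ll(y, sll, u, d1, d2, pll, i_sel):
    """Detection log-likelihood; only occupied days carry information."""
    J, D, T, I = y.shape
    s = 0.0
    for i in range(I):
        if i_sel >= 0 and i != i_sel:
            continue
        for t in range(T):
            delta = math.exp(d1[i] + d2 * pll[t])
            for d in range(D):
                if u[d, t, i] != 1:
                    continue
                for j in range(J):
                    yv = y[j, d, t, i]
                    if yv < 0:
                        break
                    p = sll[j, d, t, i] / (sll[j, d, t, i] + delta)
                    if p < _PCLIP:
                        p = _PCLIP
                    elif p > 1.0 - _PCLIP:
                        p = 1.0 - _PCLIP
                    if yv == 1:
                        s += math.log(p)
                    else:
                        s += math.log(1.0 - p)
    return s


@njit(cache=True, inline="always")
def _adapt(ls, k, alpha, sweep, n_burn):
    if sweep < n_burn:
        gain = 2.0 / math.sqrt(sweep + 10.0)
        if gain > 0.25:
            gain = 0.25
        ls[k] += gain * (alpha - 0.44)
        if ls[k] < -10.0:
            ls[k] = -10.0
        elif ls[k] > 3.0:
            ls[k] = 3.0


@njit(cache=True)
def run_chain(y, sll, pll, jday,
              effect_sd, prec_shape, prec_rate,
              n_burn, n_iter, thin, seed,
              pc, gc, epI, egI, epT, egT, d1, d2, psi1,
              update_params, store_u):
    """Run one MCMC chain; returns stacked post-burn-in draws.

    Parameter arrays are taken as initial values and mutated in place.
    """
    np.random.seed(seed)
    J, D, T, I = y.shape
    n_keep = n_iter // thin

    tau = np.ones(4)  # pI, gI, pT, gT precisions

    # step-size slots: pc(3) gc(3) epI(I) egI(I) epT(T) egT(T) d1(I) d2(1)
    n_ls = 6 + 2 * I + 2 * T + I + 1
    ls = np.full(n_ls, math.log(0.2))
    acc = np.zeros(n_ls)
    prop = np.zeros(n_ls)

    u = np.zeros((D, T, I), dtype=np.int8)
    logb0 = np.empty(D)
    logb1 = np.empty(D)
    phi = np.empty(D - 1)
    gam = np.empty(D - 1)
    a0 = np.empty(D)
    a1 = np.empty(D)
    ucol = np.empty(D, dtype=np.int8)

    pc_out = np.empty((n_keep, 3))
    gc_out = np.empty((n_keep, 3))
    epI_out = np.empty((n_keep, I))
    egI_out = np.empty((n_keep, I))
    epT_out = np.empty((n_keep, T))
    egT_out = np.empty((n_keep, T))
    d1_out = np.empty((n_keep, I))
    d2_out = np.empty(n_keep)
    psi1_out = np.empty((n_keep, T, I))
    sigma_out = np.empty((n_keep, 4))
    u_out = np.zeros((n_keep if store_u else 1, D, T, I), dtype=np.uint8)

    inv_es2 = 1.0 / (effect_sd * effect_sd)

    for sweep in range(n_burn + n_iter):
        # --- 1. latent chains, one exact joint draw per site-year -------
        for t in range(T):
            for i in range(I):
                delta = math.exp(d1[i] + d2[0] * pll[t])
                _cell_logb(y, sll, t, i, delta, logb0, logb1)
                _cell_rates(pc, epI[i], epT[t], jday, phi)
                _cell_rates(gc, egI[i], egT[t], jday, gam)
                _ffbs_cell(logb0, logb1, phi, gam, psi1[t, i], ucol, a0, a1)
                for d in range(D):
                    u[d, t, i] = ucol[d]

        if update_params:
            # --- 2. day-1 occupancy, Beta conjugate under Uniform(0,1) --
            for t in range(T):
                for i in range(I):
                    u1 = u[0, t, i]
                    psi1[t, i] = np.random.beta(1.0 + u1, 2.0 - u1)

            # --- 3a. persistence quadratic coefficients -----------------
            for k in range(3):
                cur = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, -1, -1) \
                    - 0.5 * pc[k] * pc[k] * inv_es2
                old = pc[k]
                pc[k] = old + np.random.normal() * math.exp(ls[k])
                new = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, -1, -1) \
                    - 0.5 * pc[k] * pc[k] * inv_es2
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[k] += 1
                if np.random.random() < alpha:
                    acc[k] += 1
                else:
                    pc[k] = old
                _adapt(ls, k, alpha, sweep, n_burn)

            # --- 3b. colonization quadratic coefficients ----------------
            for k in range(3):
                sk = 3 + k
                cur = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, -1, -1) \
                    - 0.5 * gc[k] * gc[k] * inv_es2
                old = gc[k]
                gc[k] = old + np.random.normal() * math.exp(ls[sk])
                new = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, -1, -1) \
                    - 0.5 * gc[k] * gc[k] * inv_es2
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    gc[k] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

            # --- 3c. site random effects --------------------------------
            for i in range(I):
                sk = 6 + i
                cur = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, i, -1) \
                    - 0.5 * tau[0] * epI[i] * epI[i]
                old = epI[i]
                epI[i] = old + np.random.normal() * math.exp(ls[sk])
                new = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, i, -1) \
                    - 0.5 * tau[0] * epI[i] * epI[i]
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    epI[i] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

                sk = 6 + I + i
                cur = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, i, -1) \
                    - 0.5 * tau[1] * egI[i] * egI[i]
                old = egI[i]
                egI[i] = old + np.random.normal() * math.exp(ls[sk])
                new = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, i, -1) \
                    - 0.5 * tau[1] * egI[i] * egI[i]
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    egI[i] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

            # --- 3d. year random effects --------------------------------
            for t in range(T):
                sk = 6 + 2 * I + t
                cur = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, -1, t) \
                    - 0.5 * tau[2] * epT[t] * epT[t]
                old = epT[t]
                epT[t] = old + np.random.normal() * math.exp(ls[sk])
                new = _pers_ll(u, jday, pc[0], pc[1], pc[2], epI, epT, -1, t) \
                    - 0.5 * tau[2] * epT[t] * epT[t]
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    epT[t] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

                sk = 6 + 2 * I + T + t
                cur = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, -1, t) \
                    - 0.5 * tau[3] * egT[t] * egT[t]
                old = egT[t]
                egT[t] = old + np.random.normal() * math.exp(ls[sk])
                new = _col_ll(u, jday, gc[0], gc[1], gc[2], egI, egT, -1, t) \
                    - 0.5 * tau[3] * egT[t] * egT[t]
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    egT[t] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

            # --- 4. random-effect precisions, Gamma conjugate -----------
            tau[0] = np.random.gamma(prec_shape + 0.5 * I,
                                     1.0 / (prec_rate + 0.5 * np.sum(epI * epI)))
            tau[1] = np.random.gamma(prec_shape + 0.5 * I,
                                     1.0 / (prec_rate + 0.5 * np.sum(egI * egI)))
            tau[2] = np.random.gamma(prec_shape + 0.5 * T,
                                     1.0 / (prec_rate + 0.5 * np.sum(epT * epT)))
            tau[3] = np.random.gamma(prec_shape + 0.5 * T,
                                     1.0 / (prec_rate + 0.5 * np.sum(egT * egT)))

            # --- 5. detection coefficients ------------------------------
            for i in range(I):
                sk = 6 + 2 * I + 2 * T + i
                cur = _det_ll(y, sll, u, d1, d2[0], pll, i) \
                    - 0.5 * d1[i] * d1[i] * inv_es2
                old = d1[i]
                d1[i] = old + np.random.normal() * math.exp(ls[sk])
                new = _det_ll(y, sll, u, d1, d2[0], pll, i) \
                    - 0.5 * d1[i] * d1[i] * inv_es2
                lr = new - cur
                alpha = math.exp(lr) if lr < 0.0 else 1.0
                prop[sk] += 1
                if np.random.random() < alpha:
                    acc[sk] += 1
                else:
                    d1[i] = old
                _adapt(ls, sk, alpha, sweep, n_burn)

            sk = 6 + 2 * I + 2 * T + I
            cur = _det_ll(y, sll, u, d1, d2[0], pll, -1) \
                - 0.5 * d2[0] * d2[0] * inv_es2
            old = d2[0]
            d2[0] = old + np.random.normal() * math.exp(ls[sk])
            new = _det_ll(y, sll, u, d1, d2[0], pll, -1) \
                - 0.5 * d2[0] * d2[0] * inv_es2
            lr = new - cur
            alpha = math.exp(lr) if lr < 0.0 else 1.0
            prop[sk] += 1
            if np.random.random() < alpha:
                acc[sk] += 1
            else:
                d2[0] = old
            _adapt(ls, sk, alpha, sweep, n_burn)

        # --- store ------------------------------------------------------
        if sweep >= n_burn:
            k = sweep - n_burn
            if k % thin == 0:
                s = k // thin
                if s < n_keep:
                    pc_out[s] = pc
                    gc_out[s] = gc
                    epI_out[s] = epI
                    egI_out[s] = egI
                    epT_out[s] = epT
                    egT_out[s] = egT
                    d1_out[s] = d1
                    d2_out[s] = d2[0]
                    psi1_out[s] = psi1
                    for q in range(4):
                        sigma_out[s, q] = 1.0 / math.sqrt(tau[q])
                    if store_u:
                        for d in range(D):
                            for t in range(T):
                                for i in range(I):
                                    u_out[s, d, t, i] = u[d, t, i]

    rate = np.zeros(n_ls)
    for k in range(n_ls):
        if prop[k] > 0:
            rate[k] = acc[k] / prop[k]
    return (pc_out, gc_out, epI_out, egI_out, epT_out, egT_out,
            d1_out, d2_out, psi1_out, sigma_out, u_out, rate)
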