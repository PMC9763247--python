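"""Numba-compiled MCMC kernels.

Two samplers live here: the piecewise birth-death sampler with joint
preservation modelling (occurrence mode) or fixed lifespans (combined mode),
and the covariate-driven multivariate birth-death sampler with horseshoe
Gibbs updates.  Everything is plain arrays; the public modules wrap these in
typed containers.

Conventions: ages in Ma before present; shift-grid edges descending with the
last edge at 0; a bin spans [edges[j+1], edges[j]) with the oldest bin closed
at the origin edge.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Across-species preservation-rate heterogeneity is integrated out in closed
# form: with a Gamma(alpha, rate alpha) multiplier m on a Poisson process
# with cumulative intensity L and n events of log-intensity slogq,
#   log lik = slogq + lgamma(alpha+n) - lgamma(alpha)
#             + alpha*log(alpha) - (alpha+n)*log(alpha+L).


@njit(cache=True)
def _bin_of(age, edges):
    nb = edges.shape[0] - 1
    if age >= edges[0]:
        return 0
    for j in range(nb):
        if edges[j + 1] <= age < edges[j]:
            return j
    return nb - 1


@njit(cache=True)
def _bd_stats(ts, te, edges, B, D, S):
    n = ts.shape[0]
    nb = edges.shape[0] - 1
    for j in range(nb):
        B[j] = 0.0
        D[j] = 0.0
        S[j] = 0.0
    imax = 0
    for i in range(1, n):
        if ts[i] > ts[imax]:
            imax = i
    for i in range(n):
        if i != imax:
            B[_bin_of(ts[i], edges)] += 1.0
        if te[i] > 0.0:
            D[_bin_of(te[i], edges)] += 1.0
        for j in range(nb):
            hi = ts[i] if ts[i] < edges[j] else edges[j]
            lo = te[i] if te[i] > edges[j + 1] else edges[j + 1]
            if hi > lo:
                S[j] += hi - lo


@njit(cache=True)
def _bd_ll(B, D, S, lam, mu):
    ll = 0.0
    for j in range(B.shape[0]):
        if B[j] > 0.0:
            if lam[j] <= 0.0:
                return -np.inf
            ll += B[j] * math.log(lam[j])
        if D[j] > 0.0:
            if mu[j] <= 0.0:
                return -np.inf
            ll += D[j] * math.log(mu[j])
        ll -= (lam[j] + mu[j]) * S[j]
    return ll


@njit(cache=True)
def _pres_ll(ts, te, edges_q, qv, alpha, c, n_occ, has_occ, use_gamma):
    n = ts.shape[0]
    nq = qv.shape[0]
    ll = 0.0
    for i in range(n):
        if has_occ[i] == 0:
            continue
        lam_int = 0.0
        slogq = 0.0
        for l in range(nq):
            hi = ts[i] if ts[i] < edges_q[l] else edges_q[l]
            lo = te[i] if te[i] > edges_q[l + 1] else edges_q[l + 1]
            if hi > lo:
                lam_int += qv[l] * (hi - lo)
            if c[i, l] > 0:
                slogq += c[i, l] * math.log(qv[l])
        if use_gamma:
            ll += (
                slogq
                + math.lgamma(alpha + n_occ[i])
                - math.lgamma(alpha)
                + alpha * math.log(alpha)
                - (alpha + n_occ[i]) * math.log(alpha + lam_int)
            )
        else:
            ll += slogq - lam_int
    return ll


@njit(cache=True)
def _gamma_logprior(x, shape, rate):
    return (shape - 1.0) * math.log(x) - rate * x


@njit(cache=True)
def _reflect(x, lo, hi):
    width = hi - lo
    if width <= 0.0:
        return lo
    y = (x - lo) % (2.0 * width)
    if y < 0.0:
        y += 2.0 * width
    if y > width:
        y = 2.0 * width - y
    return lo + y


@njit(cache=True)
def run_bdcs_chain(
    seed,
    n_iter,
    sample_freq,
    edges_bd,
    edges_q,
    lam,
    mu,
    qv,
    alpha,
    ts,
    te,
    extant,
    has_occ,
    c,
    n_occ,
    max_occ,
    min_occ,
    estimate_times,
    use_preservation,
    use_gamma,
    p_rates,
    p_pres,
    mult_window,
    time_window,
    frac_time,
):
    """Metropolis-Hastings over rates, preservation parameters and species
    (ts, te); returns thinned samples of every block plus acceptance rates.

    Priors: Gamma(1.1, 1) on each rate and preservation rate, Exp(1) on the
    heterogeneity shape, flat on (ts, te) within their admissible intervals.
    """
    np.random.seed(seed)
    n = ts.shape[0]
    nb = edges_bd.shape[0] - 1
    nq = qv.shape[0]
    origin = edges_bd[0]

    B = np.zeros(nb)
    D = np.zeros(nb)
    S = np.zeros(nb)
    _bd_stats(ts, te, edges_bd, B, D, S)
    ll_bd = _bd_ll(B, D, S, lam, mu)
    ll_pres = 0.0
    if use_preservation:
        ll_pres = _pres_ll(ts, te, edges_q, qv, alpha, c, n_occ, has_occ, use_gamma)

    lp = 0.0
    for j in range(nb):
        lp += _gamma_logprior(lam[j], 1.1, 1.0) + _gamma_logprior(mu[j], 1.1, 1.0)
    if use_preservation:
        for l in range(nq):
            lp += _gamma_logprior(qv[l], 1.1, 1.0)
        if use_gamma:
            lp += -alpha

    n_samples = n_iter // sample_freq + 1
    out_lam = np.zeros((n_samples, nb))
    out_mu = np.zeros((n_samples, nb))
    out_q = np.zeros((n_samples, nq))
    out_alpha = np.zeros(n_samples)
    out_ts = np.zeros((n_samples, n))
    out_te = np.zeros((n_samples, n))
    out_ll = np.zeros(n_samples)
    out_lp = np.zeros(n_samples)

    ts_prop = ts.copy()
    te_prop = te.copy()
    Bp = np.zeros(nb)
    Dp = np.zeros(nb)
    Sp = np.zeros(nb)

    acc = np.zeros(3)
    tries = np.zeros(3)
    k = 0
    out_lam[0] = lam
    out_mu[0] = mu
    out_q[0] = qv
    out_alpha[0] = alpha
    out_ts[0] = ts
    out_te[0] = te
    out_ll[0] = ll_bd + ll_pres
    out_lp[0] = lp

    p_pres_eff = p_pres if use_preservation else 0.0
    p_rates_eff = p_rates if estimate_times or use_preservation else 1.0

    for it in range(1, n_iter + 1):
        u = np.random.random()
        if u < p_rates_eff:
            # one birth-death rate, log-scale multiplier move
            tries[0] += 1.0
            idx = int(np.random.random() * (2 * nb))
            if idx >= 2 * nb:
                idx = 2 * nb - 1
            m = math.exp(mult_window * (np.random.random() - 0.5))
            if idx < nb:
                old = lam[idx]
                new = old * m
                d_ll = -(new - old) * S[idx]
                if B[idx] > 0.0:
                    d_ll += B[idx] * (math.log(new) - math.log(old))
            else:
                jdx = idx - nb
                old = mu[jdx]
                new = old * m
                d_ll = -(new - old) * S[jdx]
                if D[jdx] > 0.0:
                    d_ll += D[jdx] * (math.log(new) - math.log(old))
            d_lp = _gamma_logprior(new, 1.1, 1.0) - _gamma_logprior(old, 1.1, 1.0)
            if math.log(np.random.random()) < d_ll + d_lp + math.log(m):
                acc[0] += 1.0
                ll_bd += d_ll
                lp += d_lp
                if idx < nb:
                    lam[idx] = new
                else:
                    mu[idx - nb] = new
        elif u < p_rates_eff + p_pres_eff:
            # preservation rate or heterogeneity shape
            tries[1] += 1.0
            n_par = nq + (1 if use_gamma else 0)
            idx = int(np.random.random() * n_par)
            if idx >= n_par:
                idx = n_par - 1
            m = math.exp(mult_window * (np.random.random() - 0.5))
            if idx < nq:
                old = qv[idx]
                qv[idx] = old * m
                new_pres = _pres_ll(ts, te, edges_q, qv, alpha, c, n_occ, has_occ, use_gamma)
                d_lp = _gamma_logprior(qv[idx], 1.1, 1.0) - _gamma_logprior(old, 1.1, 1.0)
                if math.log(np.random.random()) < new_pres - ll_pres + d_lp + math.log(m):
                    acc[1] += 1.0
                    ll_pres = new_pres
                    lp += d_lp
                else:
                    qv[idx] = old
            else:
                old = alpha
                new_alpha = old * m
                new_pres = _pres_ll(ts, te, edges_q, qv, new_alpha, c, n_occ, has_occ, use_gamma)
                d_lp = -(new_alpha - old)
                if math.log(np.random.random()) < new_pres - ll_pres + d_lp + math.log(m):
                    acc[1] += 1.0
                    ll_pres = new_pres
                    lp += d_lp
                    alpha = new_alpha
        else:
            # sliding-window (reflected) update of a random subset of (ts, te)
            tries[2] += 1.0
            for i in range(n):
                ts_prop[i] = ts[i]
                te_prop[i] = te[i]
            n_sel = 0
            for i in range(n):
                if np.random.random() < frac_time:
                    n_sel += 1
                    if extant[i] == 0:
                        hi_te = min_occ[i] if has_occ[i] == 1 else ts[i]
                        step = (np.random.random() - 0.5) * time_window
                        te_prop[i] = _reflect(te[i] + step, 0.0, hi_te)
                    lo_ts = max_occ[i] if has_occ[i] == 1 else 1e-6
                    step = (np.random.random() - 0.5) * time_window
                    ts_prop[i] = _reflect(ts[i] + step, lo_ts, origin)
                    if ts_prop[i] <= te_prop[i]:
                        ts_prop[i] = ts[i]
                        te_prop[i] = te[i]
            if n_sel > 0:
                _bd_stats(ts_prop, te_prop, edges_bd, Bp, Dp, Sp)
                new_bd = _bd_ll(Bp, Dp, Sp, lam, mu)
                new_pres = ll_pres
                if use_preservation:
                    new_pres = _pres_ll(
                        ts_prop, te_prop, edges_q, qv, alpha, c, n_occ, has_occ, use_gamma
                    )
                if math.log(np.random.random()) < (new_bd + new_pres) - (ll_bd + ll_pres):
                    acc[2] += 1.0
                    ll_bd = new_bd
                    ll_pres = new_pres
                    for i in range(n):
                        ts[i] = ts_prop[i]
                        te[i] = te_prop[i]
                    for j in range(nb):
                        B[j] = Bp[j]
                        D[j] = Dp[j]
                        S[j] = Sp[j]
        if it % sample_freq == 0:
            k += 1
            out_lam[k] = lam
            out_mu[k] = mu
            out_q[k] = qv
            out_alpha[k] = alpha
            out_ts[k] = ts
            out_te[k] = te
            out_ll[k] = ll_bd + ll_pres
            out_lp[k] = lp

    for b in range(3):
        if tries[b] > 0.0:
            acc[b] /= tries[b]
    return out_lam, out_mu, out_q, out_alpha, out_ts, out_te, out_ll, out_lp, acc


@njit(cache=True)
def _inv_gamma(shape, scale):
    # clamped to keep the scale-mixture Gibbs sweep away from degenerate
    # 0/inf spirals when every coefficient sits at exactly 0
    x = scale / np.random.gamma(shape, 1.0)
    if x < 1e-12:
        return 1e-12
    if x > 1e12:
        return 1e12
    return x


@njit(cache=True)
def run_mbd_chain(
    seed,
    n_iter,
    sample_freq,
    n_birth,
    n_death,
    colsum_birth,
    colsum_death,
    Cgrid,
    wN,
    lam0,
    mu0,
    gl,
    gm,
    g_scales,
    mult_window,
):
    """Multivariate birth-death sampler with horseshoe prior on the
    correlation coefficients.

    Coefficients G ~ N(0, tau^2 eps_i^2); the local (eps) and global (tau)
    scales are half-Cauchy(0, 1) and updated by the inverse-gamma
    auxiliary-variable Gibbs scheme; baselines carry Gamma(1.1, 1) priors and
    move by log-scale multipliers; each G moves by a Gaussian random walk.
    """
    np.random.seed(seed)
    ncov = gl.shape[0]
    p = 2 * ncov
    T = wN.shape[0]

    eps2 = np.ones(p)
    nu = np.ones(p)
    tau2 = 1.0
    xi = 1.0

    el = np.zeros(T)
    em = np.zeros(T)
    for t in range(T):
        sl = 0.0
        sm = 0.0
        for i in range(ncov):
            sl += Cgrid[t, i] * gl[i]
            sm += Cgrid[t, i] * gm[i]
        el[t] = math.exp(sl)
        em[t] = math.exp(sm)
    Il = 0.0
    Im = 0.0
    for t in range(T):
        Il += wN[t] * el[t]
        Im += wN[t] * em[t]

    def_ll_l = 0.0
    def_ll_m = 0.0
    for i in range(ncov):
        def_ll_l += gl[i] * colsum_birth[i]
        def_ll_m += gm[i] * colsum_death[i]
    ll = (
        n_birth * math.log(lam0)
        + def_ll_l
        + n_death * math.log(mu0)
        + def_ll_m
        - lam0 * Il
        - mu0 * Im
    )

    n_samples = n_iter // sample_freq + 1
    out_l0 = np.zeros(n_samples)
    out_m0 = np.zeros(n_samples)
    out_gl = np.zeros((n_samples, ncov))
    out_gm = np.zeros((n_samples, ncov))
    out_eps = np.zeros((n_samples, p))
    out_tau = np.zeros(n_samples)
    out_ll = np.zeros(n_samples)
    acc = np.zeros(4)
    tries = np.zeros(4)

    out_l0[0] = lam0
    out_m0[0] = mu0
    out_gl[0] = gl
    out_gm[0] = gm
    for i in range(p):
        out_eps[0, i] = math.sqrt(eps2[i])
    out_tau[0] = math.sqrt(tau2)
    out_ll[0] = ll

    enew = np.zeros(T)
    emnew = np.zeros(T)
    k = 0
    for it in range(1, n_iter + 1):
        u_block = np.random.random()
        if u_block < 0.2:
            # baseline rate multiplier move
            tries[0] += 1.0
            m = math.exp(mult_window * (np.random.random() - 0.5))
            if np.random.random() < 0.5:
                new = lam0 * m
                d_ll = n_birth * math.log(m) - (new - lam0) * Il
                d_lp = _gamma_logprior(new, 1.1, 1.0) - _gamma_logprior(lam0, 1.1, 1.0)
                if math.log(np.random.random()) < d_ll + d_lp + math.log(m):
                    acc[0] += 1.0
                    lam0 = new
                    ll += d_ll
            else:
                new = mu0 * m
                d_ll = n_death * math.log(m) - (new - mu0) * Im
                d_lp = _gamma_logprior(new, 1.1, 1.0) - _gamma_logprior(mu0, 1.1, 1.0)
                if math.log(np.random.random()) < d_ll + d_lp + math.log(m):
                    acc[0] += 1.0
                    mu0 = new
                    ll += d_ll
        elif u_block < 0.65:
            # Gaussian random-walk move on one correlation coefficient
            tries[1] += 1.0
            idx = int(np.random.random() * p)
            if idx >= p:
                idx = p - 1
            on_lambda = idx < ncov
            i = idx if on_lambda else idx - ncov
            g_old = gl[i] if on_lambda else gm[i]
            # half the proposals use the likelihood scale, half the current
            # prior scale (keeps the walk ergodic when tau*eps is tiny)
            if np.random.random() < 0.5:
                step_sd = g_scales[i]
            else:
                step_sd = 2.0 * math.sqrt(tau2 * eps2[idx]) + 1e-8
            g_new = g_old + np.random.normal(0.0, step_sd)
            for t in range(T):
                s = 0.0
                for j in range(ncov):
                    gj = gl[j] if on_lambda else gm[j]
                    if j == i:
                        gj = g_new
                    s += Cgrid[t, j] * gj
                enew[t] = math.exp(s)
            Inew = 0.0
            for t in range(T):
                Inew += wN[t] * enew[t]
            if on_lambda:
                d_ll = (g_new - g_old) * colsum_birth[i] - lam0 * (Inew - Il)
            else:
                d_ll = (g_new - g_old) * colsum_death[i] - mu0 * (Inew - Im)
            var = tau2 * eps2[idx]
            d_lp = -(g_new * g_new - g_old * g_old) / (2.0 * var)
            if math.log(np.random.random()) < d_ll + d_lp:
                acc[1] += 1.0
                ll += d_ll
                if on_lambda:
                    gl[i] = g_new
                    Il = Inew
                    for t in range(T):
                        el[t] = enew[t]
                else:
                    gm[i] = g_new
                    Im = Inew
                    for t in range(T):
                        em[t] = enew[t]
        elif u_block < 0.85:
            # joint rescaling of (G_i, eps_i): escapes the shrinkage funnel
            # where the centered Gibbs scheme would freeze a coefficient at 0
            tries[2] += 1.0
            idx = int(np.random.random() * p)
            if idx >= p:
                idx = p - 1
            on_lambda = idx < ncov
            i = idx if on_lambda else idx - ncov
            s = math.exp(mult_window * (np.random.random() - 0.5))
            g_old = gl[i] if on_lambda else gm[i]
            g_new = s * g_old
            for t in range(T):
                acc_s = 0.0
                for j in range(ncov):
                    gj = gl[j] if on_lambda else gm[j]
                    if j == i:
                        gj = g_new
                    acc_s += Cgrid[t, j] * gj
                enew[t] = math.exp(acc_s)
            Inew = 0.0
            for t in range(T):
                Inew += wN[t] * enew[t]
            if on_lambda:
                d_ll = (g_new - g_old) * colsum_birth[i] - lam0 * (Inew - Il)
            else:
                d_ll = (g_new - g_old) * colsum_death[i] - mu0 * (Inew - Im)
            d_lp = -math.log(s) - (1.0 / nu[idx]) * (1.0 / (s * s) - 1.0) / eps2[idx]
            if math.log(np.random.random()) < d_ll + d_lp:
                acc[2] += 1.0
                ll += d_ll
                eps2[idx] = min(max(eps2[idx] * s * s, 1e-12), 1e12)
                if on_lambda:
                    gl[i] = g_new
                    Il = Inew
                    for t in range(T):
                        el[t] = enew[t]
                else:
                    gm[i] = g_new
                    Im = Inew
                    for t in range(T):
                        em[t] = enew[t]
        else:
            # joint rescaling of (all G, tau): global funnel escape
            tries[3] += 1.0
            s = math.exp(mult_window * (np.random.random() - 0.5))
            for t in range(T):
                sl = 0.0
                sm = 0.0
                for j in range(ncov):
                    sl += Cgrid[t, j] * gl[j]
                    sm += Cgrid[t, j] * gm[j]
                enew[t] = math.exp(s * sl)
                emnew[t] = math.exp(s * sm)
            Il_new = 0.0
            Im_new = 0.0
            for t in range(T):
                Il_new += wN[t] * enew[t]
                Im_new += wN[t] * emnew[t]
            lin = 0.0
            for j in range(ncov):
                lin += gl[j] * colsum_birth[j] + gm[j] * colsum_death[j]
            d_ll = (s - 1.0) * lin - lam0 * (Il_new - Il) - mu0 * (Im_new - Im)
            d_lp = -math.log(s) - (1.0 / xi) * (1.0 / (s * s) - 1.0) / tau2
            if math.log(np.random.random()) < d_ll + d_lp:
                acc[3] += 1.0
                ll += d_ll
                tau2 = min(max(tau2 * s * s, 1e-12), 1e12)
                for j in range(ncov):
                    gl[j] *= s
                    gm[j] *= s
                Il = Il_new
                Im = Im_new
                for t in range(T):
                    el[t] = enew[t]
                    em[t] = emnew[t]
        # exact Gibbs sweep on the horseshoe scales
        ssum = 0.0
        for idx in range(p):
            g = gl[idx] if idx < ncov else gm[idx - ncov]
            eps2[idx] = _inv_gamma(1.0, 1.0 / nu[idx] + g * g / (2.0 * tau2))
            nu[idx] = _inv_gamma(1.0, 1.0 + 1.0 / eps2[idx])
            ssum += g * g / eps2[idx]
        tau2 = _inv_gamma(0.5 * (p + 1.0), 1.0 / xi + 0.5 * ssum)
        xi = _inv_gamma(1.0, 1.0 + 1.0 / tau2)

        if it % sample_freq == 0:
            k += 1
            out_l0[k] = lam0
            out_m0[k] = mu0
            out_gl[k] = gl
            out_gm[k] = gm
            for i in range(p):
                out_eps[k, i] = math.sqrt(eps2[i])
            out_tau[k] = math.sqrt(tau2)
            out_ll[k] = ll

    for b in range(4):
        if tries[b] > 0.0:
            acc[b] /= tries[b]
    return out_l0, out_m0, out_gl, out_gm, out_eps, out_tau, out_ll, acc
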