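"""Numba Gibbs-sampler kernels for whole-genome regression.

Single-site samplers with residual updating: the running residual
e = y - Xb - (genetic term) is adjusted in place after every coordinate
move, so one full scan costs O(nm) regardless of the prior family. Design
matrices arrive transposed (predictors x individuals) so each coordinate's
data vector is contiguous. Missing phenotypes (candidate individuals) are
redrawn from the current model each iteration, which is exact data
augmentation and lets validation individuals ride inside the sampler.

Family codes: 0 ridge (common normal variance), 1 BayesA, 2 BayesB,
3 BayesCpi, 4 Bayesian LASSO. The GBLUP kernel works in the eigenbasis of
the genomic relationship matrix, where the breeding-value coordinates are
conditionally independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RIDGE, BAYES_A, BAYES_B, BAYES_CPI, BLASSO = 0, 1, 2, 3, 4


@njit(cache=True)
def _rinvgauss(mu: float, lam: float) -> float:
    # Michael-Schucany-Haas transform
    v = np.random.normal()
    y = v * v
    x = mu + (mu * mu * y) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _scaled_inv_chi2(df: float, scale_times_df: float) -> float:
    # draw from ScInvChi2(df, S) given S*df
    return scale_times_df / np.random.chisquare(df)


@njit(cache=True)
def marker_gibbs(
    y0,
    miss,  # bool mask of missing phenotypes
    XT,  # fixed-effect design, transposed (p x n), rows contiguous
    WT,  # centered dosages, transposed (m x n), rows contiguous
    family,
    nu,
    s_alpha,
    estimate_scale,
    s_shape,
    s_rate,
    pi0,
    estimate_pi,
    lam2_0,
    lam_shape,
    lam_rate,
    nu_e,
    s_e,
    n_iter,
    burn,
    thin,
    seed,
    save_effects,
    debug,
):
    np.random.seed(seed)
    m, n = WT.shape
    p = XT.shape[0]

    xtx = np.empty(p)
    for k in range(p):
        xtx[k] = np.dot(XT[k], XT[k])
    wtw = np.empty(m)
    for j in range(m):
        wtw[j] = np.dot(WT[j], WT[j])

    y = y0.copy()
    obs_mean = 0.0
    n_obs = 0
    for i in range(n):
        if not miss[i]:
            obs_mean += y[i]
            n_obs += 1
    obs_mean = obs_mean / max(n_obs, 1)
    for i in range(n):
        if miss[i]:
            y[i] = obs_mean

    b = np.zeros(p)
    alpha = np.zeros(m)
    delta = np.ones(m, dtype=np.int64)  # inclusion indicators (BayesB/Cpi)
    if family == BAYES_B or family == BAYES_CPI:
        for j in range(m):
            if np.random.random() < pi0:
                delta[j] = 0
    sig2j = np.full(m, s_alpha)  # per-marker variances (BayesA/B)
    sig2_alpha = s_alpha  # common variance (ridge/BayesCpi)
    tau2 = np.full(m, 2.0 / max(lam2_0, 1e-12))
    lam2 = lam2_0
    pi = pi0
    sig2e = s_e

    e = y.copy()  # residual: alpha = 0, b = 0 at start

    n_store = 0
    for it in range(n_iter):
        if it >= burn and (it - burn) % thin == 0:
            n_store += 1
    b_draws = np.zeros((n_store, p))
    sig2a_draws = np.zeros(n_store)
    sig2e_draws = np.zeros(n_store)
    pi_draws = np.zeros(n_store)
    lam2_draws = np.zeros(n_store)
    alpha_mean = np.zeros(m)
    g_mean = np.zeros(n)
    if save_effects:
        alpha_draws = np.zeros((n_store, m))
    else:
        alpha_draws = np.zeros((1, 1))
    max_resid_dev = 0.0

    store = 0
    for it in range(n_iter):
        # data augmentation for candidate individuals
        sde = np.sqrt(sig2e)
        for i in range(n):
            if miss[i]:
                fitted = y[i] - e[i]
                noise = sde * np.random.normal()
                y[i] = fitted + noise
                e[i] = noise

        # fixed effects, flat prior
        for k in range(p):
            rhs = np.dot(XT[k], e) + xtx[k] * b[k]
            mean = rhs / xtx[k]
            bnew = mean + np.random.normal() * np.sqrt(sig2e / xtx[k])
            diff = b[k] - bnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += XT[k, i] * diff
            b[k] = bnew

        # learn the scale of the marker-variance prior (conjugate Gamma);
        # a fixed scale acts as a floor on the genetic variance when m >> n
        if estimate_scale:
            if family == BAYES_A or family == BAYES_B:
                inv_sum = 0.0
                for j in range(m):
                    inv_sum += 1.0 / sig2j[j]
                s_alpha = np.random.gamma(
                    s_shape + 0.5 * nu * m, 1.0 / (s_rate + 0.5 * nu * inv_sum)
                )
            elif family == RIDGE or family == BAYES_CPI:
                s_alpha = np.random.gamma(
                    s_shape + 0.5 * nu, 1.0 / (s_rate + 0.5 * nu / sig2_alpha)
                )

        # marker effects
        if family == RIDGE or family == BAYES_A:
            ssq = 0.0
            for j in range(m):
                sj = sig2_alpha if family == RIDGE else sig2j[j]
                lhs = wtw[j] + sig2e / sj
                rhs = np.dot(WT[j], e) + wtw[j] * alpha[j]
                mean = rhs / lhs
                anew = mean + np.random.normal() * np.sqrt(sig2e / lhs)
                diff = alpha[j] - anew
                for i in range(n):
                    e[i] += WT[j, i] * diff
                alpha[j] = anew
                if family == BAYES_A:
                    sig2j[j] = _scaled_inv_chi2(nu + 1.0, nu * s_alpha + anew * anew)
                else:
                    ssq += anew * anew
            if family == RIDGE:
                sig2_alpha = _scaled_inv_chi2(nu + m, nu * s_alpha + ssq)
        elif family == BAYES_B or family == BAYES_CPI:
            n_in = 0
            ssq_in = 0.0
            for j in range(m):
                sj = sig2j[j] if family == BAYES_B else sig2_alpha
                # rhs uses the residual with marker j's effect added back
                rhs = np.dot(WT[j], e) + wtw[j] * alpha[j]
                v0 = wtw[j] * sig2e
                v1 = v0 + wtw[j] * wtw[j] * sj
                log_ratio = 0.5 * (np.log(v0 / v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1))
                pi_c = min(max(pi, 1e-12), 1.0 - 1e-12)
                log_odds = np.log((1.0 - pi_c) / pi_c) + log_ratio  # included vs zero
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    lhs = wtw[j] + sig2e / sj
                    mean = rhs / lhs
                    anew = mean + np.random.normal() * np.sqrt(sig2e / lhs)
                    delta[j] = 1
                    n_in += 1
                    ssq_in += anew * anew
                    if family == BAYES_B:
                        sig2j[j] = _scaled_inv_chi2(nu + 1.0, nu * s_alpha + anew * anew)
                else:
                    anew = 0.0
                    delta[j] = 0
                    if family == BAYES_B:
                        # refresh from the prior to keep the hierarchy proper
                        sig2j[j] = _scaled_inv_chi2(nu, nu * s_alpha)
                diff = alpha[j] - anew
                if diff != 0.0:
                    for i in range(n):
                        e[i] += WT[j, i] * diff
                alpha[j] = anew
            if family == BAYES_CPI:
                sig2_alpha = _scaled_inv_chi2(nu + n_in, nu * s_alpha + ssq_in)
            if estimate_pi:
                pi = np.random.beta(m - n_in + 1.0, n_in + 1.0)
        else:  # BLASSO: alpha_j | tau2_j ~ N(0, tau2_j), tau2_j ~ Exp(lam2/2)
            for j in range(m):
                lhs = wtw[j] + sig2e / tau2[j]
                rhs = np.dot(WT[j], e) + wtw[j] * alpha[j]
                mean = rhs / lhs
                anew = mean + np.random.normal() * np.sqrt(sig2e / lhs)
                diff = alpha[j] - anew
                for i in range(n):
                    e[i] += WT[j, i] * diff
                alpha[j] = anew
                a2 = anew * anew
                if a2 < 1e-14:
                    # effect at zero: conditional reduces to the Exp(lam2/2) prior
                    tau2[j] = np.random.exponential(2.0 / lam2)
                else:
                    inv_tau2 = _rinvgauss(np.sqrt(lam2 / a2), lam2)
                    tau2[j] = 1.0 / inv_tau2
            sum_tau2 = 0.0
            for j in range(m):
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(lam_shape + m, 1.0 / (lam_rate + 0.5 * sum_tau2))

        # residual variance
        sse = np.dot(e, e)
        sig2e = _scaled_inv_chi2(nu_e + n, nu_e * s_e + sse)

        if it >= burn and (it - burn) % thin == 0:
            g = WT.T @ alpha
            gbar = 0.0
            for i in range(n):
                gbar += g[i]
            gbar /= n
            va = 0.0
            for i in range(n):
                va += (g[i] - gbar) ** 2
            va /= n
            for k in range(p):
                b_draws[store, k] = b[k]
            sig2a_draws[store] = va
            sig2e_draws[store] = sig2e
            pi_draws[store] = pi
            lam2_draws[store] = lam2
            for j in range(m):
                alpha_mean[j] += alpha[j]
            for i in range(n):
                g_mean[i] += g[i]
            if save_effects:
                for j in range(m):
                    alpha_draws[store, j] = alpha[j]
            if debug:
                recon = y - XT.T @ b - g
                dev = 0.0
                for i in range(n):
                    d_i = abs(recon[i] - e[i])
                    if d_i > dev:
                        dev = d_i
                if dev > max_resid_dev:
                    max_resid_dev = dev
            store += 1

    if n_store > 0:
        for j in range(m):
            alpha_mean[j] /= n_store
        for i in range(n):
            g_mean[i] /= n_store
    return (
        b_draws,
        sig2a_draws,
        sig2e_draws,
        pi_draws,
        lam2_draws,
        alpha_mean,
        g_mean,
        alpha_draws,
        max_resid_dev,
    )


@njit(cache=True)
def gblup_gibbs(
    y0,
    miss,
    XT,  # fixed-effect design, transposed (p x n)
    U,  # eigenvectors of G (columns)
    d,  # eigenvalues of G, non-negative (zeros = null space)
    nu_a,
    s_a,
    nu_e,
    s_e,
    n_iter,
    burn,
    thin,
    seed,
    save_u,
    debug,
):
    np.random.seed(seed)
    n = U.shape[0]
    p = XT.shape[0]

    xtx = np.empty(p)
    for k in range(p):
        xtx[k] = np.dot(XT[k], XT[k])

    n_pos = 0
    for i in range(n):
        if d[i] > 0.0:
            n_pos += 1

    y = y0.copy()
    obs_mean = 0.0
    n_obs = 0
    for i in range(n):
        if not miss[i]:
            obs_mean += y[i]
            n_obs += 1
    obs_mean /= max(n_obs, 1)
    for i in range(n):
        if miss[i]:
            y[i] = obs_mean

    b = np.zeros(p)
    v = np.zeros(n)  # breeding values in the eigenbasis
    u = np.zeros(n)
    sig2a = s_a
    sig2e = s_e
    e = y.copy()

    n_store = 0
    for it in range(n_iter):
        if it >= burn and (it - burn) % thin == 0:
            n_store += 1
    b_draws = np.zeros((n_store, p))
    sig2a_draws = np.zeros(n_store)
    sig2e_draws = np.zeros(n_store)
    u_mean = np.zeros(n)
    if save_u:
        u_draws = np.zeros((n_store, n))
    else:
        u_draws = np.zeros((1, 1))
    max_resid_dev = 0.0

    store = 0
    for it in range(n_iter):
        sde = np.sqrt(sig2e)
        for i in range(n):
            if miss[i]:
                fitted = y[i] - e[i]
                noise = sde * np.random.normal()
                y[i] = fitted + noise
                e[i] = noise

        for k in range(p):
            rhs = np.dot(XT[k], e) + xtx[k] * b[k]
            mean = rhs / xtx[k]
            bnew = mean + np.random.normal() * np.sqrt(sig2e / xtx[k])
            diff = b[k] - bnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += XT[k, i] * diff
            b[k] = bnew

        # breeding values: rotate the partial residual once, update each
        # eigen-coordinate independently, rotate back
        r = e + u  # y - Xb
        t = U.T @ r
        ssq_scaled = 0.0
        for i in range(n):
            if d[i] > 0.0:
                prior_var = sig2a * d[i]
                post_var = 1.0 / (1.0 / sig2e + 1.0 / prior_var)
                post_mean = post_var * t[i] / sig2e
                v[i] = post_mean + np.random.normal() * np.sqrt(post_var)
                ssq_scaled += v[i] * v[i] / d[i]
            else:
                v[i] = 0.0
        u = U @ v
        for i in range(n):
            e[i] = r[i] - u[i]

        sig2a = _scaled_inv_chi2(nu_a + n_pos, nu_a * s_a + ssq_scaled)
        sse = np.dot(e, e)
        sig2e = _scaled_inv_chi2(nu_e + n, nu_e * s_e + sse)

        if it >= burn and (it - burn) % thin == 0:
            for k in range(p):
                b_draws[store, k] = b[k]
            sig2a_draws[store] = sig2a
            sig2e_draws[store] = sig2e
            for i in range(n):
                u_mean[i] += u[i]
            if save_u:
                for i in range(n):
                    u_draws[store, i] = u[i]
            if debug:
                recon = y - XT.T @ b - u
                dev = 0.0
                for i in range(n):
                    d_i = abs(recon[i] - e[i])
                    if d_i > dev:
                        dev = d_i
                if dev > max_resid_dev:
                    max_resid_dev = dev
            store += 1

    if n_store > 0:
        for i in range(n):
            u_mean[i] /= n_store
    return b_draws, sig2a_draws, sig2e_draws, u_mean, u_draws, max_resid_dev
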