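"""Numba-compiled Gibbs samplers for the Bayesian LASSO and RKHS models.

Both samplers use the scaled-inverse-chi-square residual prior expressed as
InvGamma(df/2, S/2), whose mean is S/(df-2); with df = 4 and S = 1 the prior
expectation of the residual variance is 0.5 (half of the unit sample
variance of standardized phenotypes).  Replicated phenotypes enter through
per-line weights n_i, giving residual variance sigma2_eps / n_i.

Seeding uses numba's internal RNG: identical seeds give identical chains.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["bl_gibbs", "rkhs_gibbs_orthonormal", "rkhs_gibbs_weighted"]

_TINY = 1e-300


@njit(cache=True, fastmath=True)
def _rinvgauss(mu, lam):
    """One inverse-Gaussian(mu, lam) draw (Michael-Schucany-Haas)."""
    v = np.random.standard_normal()
    v = v * v
    x = mu + (mu * mu * v) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v
    )
    if x <= 0.0:
        x = _TINY
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True, fastmath=True)
def bl_gibbs(
    y,
    XT,
    w,
    df,
    S,
    shape_l,
    rate_l,
    n_iter,
    burn,
    thin,
    seed,
    store_beta,
    lambda_fixed,
):
    """Park-Casella Gibbs sampler with per-observation weights.

    XT is the p x n transposed covariate matrix (rows contiguous per
    covariate).  ``lambda_fixed`` <= 0 means lambda^2 is sampled from its
    Gamma(shape_l, rate_l) prior-conditional; a positive value pins it.

    Returns posterior means (mu, beta, sigma2, lambda), beta posterior SDs,
    scalar chains (mu, sigma2, lambda) and an optional thinned beta chain.
    """
    np.random.seed(seed)
    p, n = XT.shape
    XW = XT * w  # p x n, row j = w * x_j
    xwx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += XW[j, i] * XT[j, i]
        xwx[j] = s
    w_sum = w.sum()

    beta = np.zeros(p)
    tau2 = np.ones(p)
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= w_sum
    sigma2 = 0.5
    if lambda_fixed > 0.0:
        lam2 = lambda_fixed * lambda_fixed
    else:
        lam2 = 900.0  # near the induced prior mode of lambda

    r = y - mu  # residual y - mu - X beta

    n_samples = (n_iter - burn + thin - 1) // thin
    chain_mu = np.empty(n_samples)
    chain_sigma2 = np.empty(n_samples)
    chain_lambda = np.empty(n_samples)
    if store_beta:
        chain_beta = np.empty((n_samples, p))
    else:
        chain_beta = np.empty((0, p))
    beta_sum = np.zeros(p)
    beta_sq = np.zeros(p)
    mu_sum = 0.0
    sigma2_sum = 0.0
    lam_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # mu | rest (flat prior)
        num = 0.0
        for i in range(n):
            num += w[i] * (r[i] + mu)
        mu_new = num / w_sum + np.sqrt(sigma2 / w_sum) * np.random.standard_normal()
        for i in range(n):
            r[i] += mu - mu_new
        mu = mu_new

        # beta_j | rest, then 1/tau2_j | rest
        for j in range(p):
            bj = beta[j]
            c = xwx[j] + 1.0 / tau2[j]
            xr = 0.0
            for i in range(n):
                xr += XW[j, i] * r[i]
            mean = (xr + xwx[j] * bj) / c
            bnew = mean + np.sqrt(sigma2 / c) * np.random.standard_normal()
            diff = bnew - bj
            if diff != 0.0:
                for i in range(n):
                    r[i] -= XT[j, i] * diff
            beta[j] = bnew
            b2 = bnew * bnew
            if b2 < 1e-20:
                b2 = 1e-20
            inv_tau2 = _rinvgauss(np.sqrt(lam2 * sigma2 / b2), lam2)
            if inv_tau2 < 1e-12:
                inv_tau2 = 1e-12
            elif inv_tau2 > 1e12:
                inv_tau2 = 1e12
            tau2[j] = 1.0 / inv_tau2

        # sigma2 | rest  (beta prior variance is tau2_j * sigma2)
        sse = 0.0
        for i in range(n):
            sse += w[i] * r[i] * r[i]
        btb = 0.0
        for j in range(p):
            btb += beta[j] * beta[j] / tau2[j]
        shape_s = 0.5 * (df + n + p)
        rate_s = 0.5 * (S + sse + btb)
        sigma2 = rate_s / np.random.gamma(shape_s, 1.0)

        # lambda2 | rest
        if lambda_fixed <= 0.0:
            tsum = 0.0
            for j in range(p):
                tsum += tau2[j]
            lam2 = np.random.gamma(shape_l + p, 1.0 / (rate_l + 0.5 * tsum))

        if it >= burn and (it - burn) % thin == 0:
            chain_mu[kept] = mu
            chain_sigma2[kept] = sigma2
            chain_lambda[kept] = np.sqrt(lam2)
            if store_beta:
                for j in range(p):
                    chain_beta[kept, j] = beta[j]
            for j in range(p):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
            mu_sum += mu
            sigma2_sum += sigma2
            lam_sum += np.sqrt(lam2)
            kept += 1

    beta_mean = beta_sum / kept
    beta_var = beta_sq / kept - beta_mean * beta_mean
    beta_sd = np.sqrt(np.maximum(beta_var, 0.0))
    return (
        mu_sum / kept,
        beta_mean,
        beta_sd,
        sigma2_sum / kept,
        lam_sum / kept,
        chain_mu,
        chain_sigma2,
        chain_lambda,
        chain_beta,
    )


@njit(cache=True)
def rkhs_gibbs_orthonormal(
    y,
    PhiT,
    lam,
    offsets,
    df_e,
    S_e,
    df_k,
    S_k,
    n_iter,
    burn,
    thin,
    seed,
    fix_variances,
    sigma2_k_fixed,
    sigma2_e_fixed,
):
    """Kernel-averaging sampler in the eigenbasis, unit observation weights.

    PhiT stacks the (truncated) eigenvector transposes of all kernels:
    rows ``offsets[k]:offsets[k+1]`` hold kernel k's eigenvectors (m_k x n),
    with eigenvalues in ``lam``.  Each coordinate's conditional is
    independent because the eigenvectors are orthonormal under unit weights.
    """
    np.random.seed(seed)
    n = y.shape[0]
    n_k = offsets.shape[0] - 1
    mtot = PhiT.shape[0]

    delta = np.zeros(mtot)
    u = np.zeros((n_k, n))
    sigma2_k = np.empty(n_k)
    for k in range(n_k):
        sigma2_k[k] = sigma2_k_fixed[k] if fix_variances else S_k / (df_k - 2.0)
    sigma2_e = sigma2_e_fixed if fix_variances else 0.5
    mu = y.mean()
    resid = y - mu  # y - mu - sum_k u_k

    n_samples = (n_iter - burn + thin - 1) // thin
    chain_mu = np.empty(n_samples)
    chain_sigma2_e = np.empty(n_samples)
    chain_sigma2_k = np.empty((n_samples, n_k))
    delta_sum = np.zeros(mtot)
    mu_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # mu (flat prior)
        mu_new = (resid + mu).mean() + np.sqrt(sigma2_e / n) * np.random.standard_normal()
        resid += mu - mu_new
        mu = mu_new

        for k in range(n_k):
            a, b = offsets[k], offsets[k + 1]
            Pk = PhiT[a:b]
            r = resid + u[k]  # y - mu - sum_{l != k} u_l
            c = np.dot(Pk, r)
            m_k = b - a
            dk = np.empty(m_k)
            for j in range(m_k):
                prior_var = sigma2_k[k] * lam[a + j]
                post_var = 1.0 / (1.0 / sigma2_e + 1.0 / prior_var)
                mean = post_var * c[j] / sigma2_e
                dk[j] = mean + np.sqrt(post_var) * np.random.standard_normal()
                delta[a + j] = dk[j]
            u_new = np.dot(dk, Pk)
            resid += u[k] - u_new
            u[k] = u_new
            if not fix_variances:
                ss = 0.0
                for j in range(m_k):
                    ss += dk[j] * dk[j] / lam[a + j]
                sigma2_k[k] = (0.5 * (S_k + ss)) / np.random.gamma(
                    0.5 * (df_k + m_k), 1.0
                )

        if not fix_variances:
            sse = np.dot(resid, resid)
            sigma2_e = (0.5 * (S_e + sse)) / np.random.gamma(0.5 * (df_e + n), 1.0)

        if it >= burn and (it - burn) % thin == 0:
            chain_mu[kept] = mu
            chain_sigma2_e[kept] = sigma2_e
            for k in range(n_k):
                chain_sigma2_k[kept, k] = sigma2_k[k]
            delta_sum += delta
            mu_sum += mu
            kept += 1

    return (
        mu_sum / kept,
        delta_sum / kept,
        chain_mu,
        chain_sigma2_e,
        chain_sigma2_k,
    )


@njit(cache=True, fastmath=True)
def rkhs_gibbs_weighted(
    y,
    w,
    PhiT,
    lam,
    offsets,
    df_e,
    S_e,
    df_k,
    S_k,
    n_iter,
    burn,
    thin,
    seed,
    fix_variances,
    sigma2_k_fixed,
    sigma2_e_fixed,
):
    """As :func:`rkhs_gibbs_orthonormal` but with residual variance
    sigma2_e / n_i per line (weights w = n_i), updating eigen-coordinates
    one at a time because the conditional is no longer diagonal."""
    np.random.seed(seed)
    n = y.shape[0]
    n_k = offsets.shape[0] - 1
    mtot = PhiT.shape[0]
    w_sum = w.sum()

    # phi_j' W phi_j for every stacked eigenvector
    pwp = np.empty(mtot)
    for j in range(mtot):
        s = 0.0
        for i in range(n):
            s += w[i] * PhiT[j, i] * PhiT[j, i]
        pwp[j] = s

    delta = np.zeros(mtot)
    sigma2_k = np.empty(n_k)
    for k in range(n_k):
        sigma2_k[k] = sigma2_k_fixed[k] if fix_variances else S_k / (df_k - 2.0)
    sigma2_e = sigma2_e_fixed if fix_variances else 0.5
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= w_sum
    resid = y - mu

    n_samples = (n_iter - burn + thin - 1) // thin
    chain_mu = np.empty(n_samples)
    chain_sigma2_e = np.empty(n_samples)
    chain_sigma2_k = np.empty((n_samples, n_k))
    delta_sum = np.zeros(mtot)
    mu_sum = 0.0
    kept = 0

    for it in range(n_iter):
        num = 0.0
        for i in range(n):
            num += w[i] * (resid[i] + mu)
        mu_new = num / w_sum + np.sqrt(sigma2_e / w_sum) * np.random.standard_normal()
        for i in range(n):
            resid[i] += mu - mu_new
        mu = mu_new

        for k in range(n_k):
            a, b = offsets[k], offsets[k + 1]
            for j in range(a, b):
                dj = delta[j]
                prior_prec = 1.0 / (sigma2_k[k] * lam[j])
                c = pwp[j] / sigma2_e + prior_prec
                pr = 0.0
                for i in range(n):
                    pr += w[i] * PhiT[j, i] * resid[i]
                mean = (pr / sigma2_e + pwp[j] * dj / sigma2_e) / c
                dnew = mean + np.sqrt(1.0 / c) * np.random.standard_normal()
                diff = dnew - dj
                if diff != 0.0:
                    for i in range(n):
                        resid[i] -= PhiT[j, i] * diff
                delta[j] = dnew
            if not fix_variances:
                ss = 0.0
                for j in range(a, b):
                    ss += delta[j] * delta[j] / lam[j]
                m_k = b - a
                sigma2_k[k] = (0.5 * (S_k + ss)) / np.random.gamma(
                    0.5 * (df_k + m_k), 1.0
                )

        if not fix_variances:
            sse = 0.0
            for i in range(n):
                sse += w[i] * resid[i] * resid[i]
            sigma2_e = (0.5 * (S_e + sse)) / np.random.gamma(0.5 * (df_e + n), 1.0)

        if it >= burn and (it - burn) % thin == 0:
            chain_mu[kept] = mu
            chain_sigma2_e[kept] = sigma2_e
            for k in range(n_k):
                chain_sigma2_k[kept, k] = sigma2_k[k]
            delta_sum += delta
            mu_sum += mu
            kept += 1

    return (
        mu_sum / kept,
        delta_sum / kept,
        chain_mu,
        chain_sigma2_e,
        chain_sigma2_k,
    )
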