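"""Single-site Gibbs samplers for the Bayesian marker-effect models.

These are the inner MCMC loops of Bayes A (per-marker scaled-inverse-chi²
effect variances), Bayes C (spike–slab with estimated inclusion probability)
and the Bayesian LASSO (double-exponential prior via its normal–exponential
scale mixture).  They are compiled with numba: the site-by-site updates are
inherently sequential and would dominate the runtime in pure Python.

All samplers share the same state-update pattern: a running residual vector
``e = y − mu − X beta`` is adjusted incrementally as each effect is
resampled.  Columns may belong to different effect terms (additive vs
dominance); each term carries its own prior scale, and for Bayes C its own
inclusion probability.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _scaled_inv_chi2(df, scale_sum):
    """Draw from the scaled-inverse-chi² full conditional: scale_sum/chi2_df."""
    return scale_sum / np.random.chisquare(df)


@njit(cache=True)
def _inv_gaussian(mu, lam):
    """Inverse-Gaussian draw (Michael–Schucany–Haas transformation)."""
    nu = np.random.standard_normal() ** 2
    x = mu + mu * mu * nu / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * nu + mu * mu * nu * nu
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _sample_mu(e, mu, var_e):
    n = e.shape[0]
    e += mu
    mu_new = e.mean() + np.random.standard_normal() * np.sqrt(var_e / n)
    e -= mu_new
    return mu_new


@njit(cache=True)
def bayes_a(X, y, term_id, n_terms, S_beta, df_beta, S_e, df_e, n_iter, burn_in, thin, seed):
    """Bayes A: marker effects with per-marker scaled-t shrinkage."""
    np.random.seed(seed)
    n, m = X.shape
    xx = np.empty(m)
    for j in range(m):
        xx[j] = X[:, j] @ X[:, j]
    beta = np.zeros(m)
    var_j = np.empty(m)
    for j in range(m):
        var_j[j] = S_beta[term_id[j]]
    mu = y.mean()
    e = y - mu
    var_e = max(e @ e / n, 1e-10)

    beta_sum = np.zeros(m)
    mu_sum = 0.0
    n_kept = (n_iter - burn_in) // thin
    var_e_draws = np.empty(n_kept)
    kept = 0
    for it in range(n_iter):
        mu = _sample_mu(e, mu, var_e)
        for j in range(m):
            if xx[j] <= 0.0:
                continue
            bj = beta[j]
            rhs = X[:, j] @ e + xx[j] * bj
            cj = xx[j] + var_e / var_j[j]
            bnew = rhs / cj + np.random.standard_normal() * np.sqrt(var_e / cj)
            e += X[:, j] * (bj - bnew)
            beta[j] = bnew
            var_j[j] = _scaled_inv_chi2(
                df_beta + 1.0, S_beta[term_id[j]] * df_beta + bnew * bnew
            )
        var_e = _scaled_inv_chi2(df_e + n, S_e * df_e + e @ e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            mu_sum += mu
            var_e_draws[kept] = var_e
            kept += 1
    return beta_sum / n_kept, mu_sum / n_kept, var_e_draws


@njit(cache=True)
def bayes_c(
    X, y, term_id, n_terms, S_beta, df_beta, S_e, df_e,
    pi_a, pi_b, n_iter, burn_in, thin, seed,
):
    """Bayes C: spike–slab effects with Beta(pi_a, pi_b) inclusion prior."""
    np.random.seed(seed)
    n, m = X.shape
    xx = np.empty(m)
    for j in range(m):
        xx[j] = X[:, j] @ X[:, j]
    m_term = np.zeros(n_terms)
    for j in range(m):
        m_term[term_id[j]] += 1
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    var_t = S_beta.copy()  # common slab variance per term
    pi = np.full(n_terms, pi_a / (pi_a + pi_b))
    mu = y.mean()
    e = y - mu
    var_e = max(e @ e / n, 1e-10)

    beta_sum = np.zeros(m)
    pip_sum = np.zeros(m)
    mu_sum = 0.0
    n_kept = (n_iter - burn_in) // thin
    var_e_draws = np.empty(n_kept)
    kept = 0
    for it in range(n_iter):
        mu = _sample_mu(e, mu, var_e)
        n_in = np.zeros(n_terms)
        ss_in = np.zeros(n_terms)
        for j in range(m):
            if xx[j] <= 0.0:
                continue
            t = term_id[j]
            bj = beta[j]
            r = X[:, j] @ e + xx[j] * bj  # x_j' (residual excluding j)
            cj = xx[j] + var_e / var_t[t]
            log_bf = 0.5 * (np.log(var_e / (var_t[t] * cj)) + r * r / (var_e * cj))
            # guard overflow
            if log_bf > 500.0:
                p1 = 1.0
            else:
                odds = pi[t] / (1.0 - pi[t]) * np.exp(log_bf)
                p1 = odds / (1.0 + odds)
            if np.random.random() < p1:
                bnew = r / cj + np.random.standard_normal() * np.sqrt(var_e / cj)
                delta[j] = 1
                n_in[t] += 1.0
                ss_in[t] += bnew * bnew
            else:
                bnew = 0.0
                delta[j] = 0
            if bnew != bj:
                e += X[:, j] * (bj - bnew)
            beta[j] = bnew
        for t in range(n_terms):
            var_t[t] = _scaled_inv_chi2(
                df_beta + n_in[t], S_beta[t] * df_beta + ss_in[t]
            )
            pi[t] = np.random.beta(pi_a + n_in[t], pi_b + m_term[t] - n_in[t])
            if pi[t] < 1e-6:
                pi[t] = 1e-6
            elif pi[t] > 1.0 - 1e-6:
                pi[t] = 1.0 - 1e-6
        var_e = _scaled_inv_chi2(df_e + n, S_e * df_e + e @ e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            pip_sum += delta
            mu_sum += mu
            var_e_draws[kept] = var_e
            kept += 1
    return beta_sum / n_kept, mu_sum / n_kept, var_e_draws, pip_sum / n_kept


@njit(cache=True)
def bayesian_lasso(
    X, y, term_id, n_terms, lam2_init, gamma_shape, gamma_rate,
    S_e, df_e, n_iter, burn_in, thin, seed,
):
    """Bayesian LASSO via the normal–exponential scale mixture (Park–Casella).

    Effect prior: beta_j ~ N(0, var_e * tau2_j), tau2_j ~ Exp(lam2/2) with a
    per-term Gamma hyperprior on lam2.
    """
    np.random.seed(seed)
    n, m = X.shape
    xx = np.empty(m)
    for j in range(m):
        xx[j] = X[:, j] @ X[:, j]
    m_term = np.zeros(n_terms)
    for j in range(m):
        m_term[term_id[j]] += 1
    beta = np.zeros(m)
    tau2 = np.full(m, 1.0)
    lam2 = lam2_init.copy()
    mu = y.mean()
    e = y - mu
    var_e = max(e @ e / n, 1e-10)

    beta_sum = np.zeros(m)
    mu_sum = 0.0
    n_kept = (n_iter - burn_in) // thin
    var_e_draws = np.empty(n_kept)
    kept = 0
    for it in range(n_iter):
        mu = _sample_mu(e, mu, var_e)
        for j in range(m):
            if xx[j] <= 0.0:
                continue
            bj = beta[j]
            rhs = X[:, j] @ e + xx[j] * bj
            cj = xx[j] + 1.0 / tau2[j]
            bnew = rhs / cj + np.random.standard_normal() * np.sqrt(var_e / cj)
            e += X[:, j] * (bj - bnew)
            beta[j] = bnew
            # tau2 update: 1/tau2 ~ InvGauss(sqrt(lam2 var_e / beta^2), lam2)
            b2 = bnew * bnew
            if b2 < 1e-14:
                b2 = 1e-14
            t = term_id[j]
            inv_t2 = _inv_gaussian(np.sqrt(lam2[t] * var_e / b2), lam2[t])
            tau2[j] = 1.0 / inv_t2
        for t in range(n_terms):
            s_tau = 0.0
            for j in range(m):
                if term_id[j] == t:
                    s_tau += tau2[j]
            lam2[t] = np.random.gamma(
                gamma_shape + m_term[t], 1.0 / (gamma_rate + 0.5 * s_tau)
            )
        # residual variance includes the scale-mixture prior terms
        ss_prior = 0.0
        for j in range(m):
            ss_prior += beta[j] * beta[j] / tau2[j]
        var_e = _scaled_inv_chi2(df_e + n + m, S_e * df_e + e @ e + ss_prior)
        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            mu_sum += mu
            var_e_draws[kept] = var_e
            kept += 1
    return beta_sum / n_kept, mu_sum / n_kept, var_e_draws
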