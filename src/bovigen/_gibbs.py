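"""Numba kernel for the BayesC/BayesC-pi Gibbs sampler.

Single-site updates with incremental residual bookkeeping: the residual
vector e = y - mu - X a is maintained across SNP updates, so one full sweep
costs O(nM).  The inclusion odds are computed in log space.  All draws come
from numba's global RNG seeded once per chain, so a chain is reproducible
bit-for-bit given (seed, iteration count, update order).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(y, X, n_iter, burn_in, thin, seed,
              v_a, v_e, s2_a_prior, s2_e_prior,
              pi_init, sample_pi,
              sigma2_a_init, sigma2_e_init,
              update_sigma_a, update_sigma_e, random_order):
    np.random.seed(seed)
    n = y.shape[0]
    M = X.shape[1]

    c = np.empty(M)
    for j in range(M):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        c[j] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n

    a = np.zeros(M)
    gamma = np.zeros(M, dtype=np.int8)
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    sigma2_a = sigma2_a_init
    sigma2_e = sigma2_e_init
    pi = pi_init

    n_post = n_iter - burn_in
    n_kept = (n_post + thin - 1) // thin
    effect_sum = np.zeros(M)
    incl_sum = np.zeros(M)
    mu_chain = np.empty(n_kept)
    pi_chain = np.empty(n_kept)
    s2a_chain = np.empty(n_kept)
    s2e_chain = np.empty(n_kept)
    kept = 0

    order = np.arange(M)
    for it in range(n_iter):
        # (i) general mean, flat prior
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu_new = mu + ebar + np.sqrt(sigma2_e / n) * np.random.standard_normal()
        dmu = mu - mu_new
        for i in range(n):
            e[i] += dmu
        mu = mu_new

        # (ii) SNP indicators and effects
        if random_order:
            order = np.random.permutation(M)
        m_incl = 0
        ssa = 0.0
        for jj in range(M):
            j = order[jj]
            a_old = a[j]
            if c[j] <= 0.0 or sigma2_a <= 0.0:
                gamma[j] = 0
                a[j] = 0.0
                if a_old != 0.0:
                    for i in range(n):
                        e[i] += X[i, j] * a_old
                continue
            r = c[j] * a_old
            for i in range(n):
                r += X[i, j] * e[i]
            vratio = c[j] * sigma2_a / sigma2_e
            log_lr = (-0.5 * np.log(1.0 + vratio)
                      + 0.5 * r * r * sigma2_a
                      / (sigma2_e * (sigma2_e + c[j] * sigma2_a)))
            if pi <= 0.0:
                include = True
            elif pi >= 1.0:
                include = False
            else:
                logit = np.log((1.0 - pi) / pi) + log_lr
                if logit > 35.0:
                    include = True
                elif logit < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-logit))
            if include:
                lhs = c[j] + sigma2_e / sigma2_a
                mean = r / lhs
                a_new = mean + np.sqrt(sigma2_e / lhs) * np.random.standard_normal()
                gamma[j] = 1
                m_incl += 1
                ssa += a_new * a_new
            else:
                a_new = 0.0
                gamma[j] = 0
            if a_new != a_old:
                d = a_old - a_new
                for i in range(n):
                    e[i] += X[i, j] * d
            a[j] = a_new

        # (iii) common effect variance: scaled inverse chi-square
        if update_sigma_a:
            sigma2_a = ((v_a * s2_a_prior + ssa)
                        / np.random.chisquare(v_a + m_incl))
        # (iv) residual variance
        if update_sigma_e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2_e = ((v_e * s2_e_prior + sse)
                        / np.random.chisquare(v_e + n))
            if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
                raise ValueError("residual variance left the support")
        # (v) exclusion probability: Beta full conditional (uniform prior)
        if sample_pi:
            pi = np.random.beta(M - m_incl + 1.0, m_incl + 1.0)

        # periodic residual refresh against float drift
        if (it + 1) % 2000 == 0:
            for i in range(n):
                s = y[i] - mu
                for j in range(M):
                    if a[j] != 0.0:
                        s -= X[i, j] * a[j]
                e[i] = s

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(M):
                effect_sum[j] += a[j]
                incl_sum[j] += gamma[j]
            mu_chain[kept] = mu
            pi_chain[kept] = pi
            s2a_chain[kept] = sigma2_a
            s2e_chain[kept] = sigma2_e
            kept += 1

    return (effect_sum / n_kept, incl_sum / n_kept,
            mu_chain, pi_chain, s2a_chain, s2e_chain)
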