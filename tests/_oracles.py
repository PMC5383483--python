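"""Independent oracles used only by the test suite.

These deliberately use different algorithms from the implementation: the
stationary distribution by power iteration instead of a linear solve, the
G statistic by a naive double loop, and the random-intercept integral by
dense non-adaptive Gauss-Hermite quadrature at high order.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss


def power_iteration_stationary(P, tol=1e-14, max_iter=1_000_000):
    P = np.asarray(P, dtype=float)
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(max_iter):
        nxt = pi @ P
        nxt /= nxt.sum()
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    raise RuntimeError("power iteration did not converge")


def naive_g_statistic(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    g = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                e = table[i].sum() * table[:, j].sum() / total
                g += o * np.log(o / e)
    return 2.0 * g


def quadrature_marginal_loglik(beta, sigma, x, y, group_index, n_groups):
    """Marginal log-likelihood by adaptive numerical integration (QUADPACK)."""
    from scipy.integrate import quad
    from scipy.stats import norm

    eta0 = x @ beta
    total = 0.0
    for g in range(n_groups):
        mask = group_index == g

        def cond_loglik(u):
            eta = eta0[mask] + sigma * u
            return (y[mask] * eta - np.logaddexp(0.0, eta)).sum()

        shift = cond_loglik(0.0)
        value, _ = quad(
            lambda u: np.exp(cond_loglik(u) - shift) * norm.pdf(u),
            -np.inf,
            np.inf,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        total += shift + np.log(value)
    return total
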