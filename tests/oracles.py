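"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately use dense matrix algebra and generic optimisers so they
share no code path with the package implementation.
"""

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp


def dense_grid_posterior(y, v, groups, X, tau_grid, phi_grid):
    """Posterior mean/SE of beta by dense (tau, phi) grid integration.

    Builds each full covariance matrix explicitly and uses generic inverse
    and slogdet calls; same prior family and trapezoid weights as the
    package, but none of its diagonal-plus-rank-one shortcuts.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    n = y.size
    groups = list(groups)
    same = np.array(
        [[1.0 if groups[i] == groups[j] else 0.0 for j in range(n)] for i in range(n)]
    )
    s0 = np.sqrt(n / (1.0 / v).sum())
    trap = np.full(tau_grid.size, tau_grid[1] - tau_grid[0])
    trap[0] *= 0.5
    trap[-1] *= 0.5

    logw, betas, variances = [], [], []
    for ti, tau in enumerate(tau_grid):
        for phi in phi_grid:
            M = np.where(np.eye(n) > 0, 1.0, phi * same)
            sigma = np.diag(v) + tau**2 * M
            si = np.linalg.inv(sigma)
            info = X.T @ si @ X
            b = np.linalg.solve(info, X.T @ si @ y)
            resid = y - X @ b
            ll = -0.5 * (
                np.linalg.slogdet(sigma)[1]
                + np.linalg.slogdet(info)[1]
                + resid @ si @ resid
            )
            prior = (
                np.log(s0 / (s0 + tau) ** 2)
                + np.log(trap[ti])
                - np.log(len(phi_grid))
            )
            logw.append(ll + prior)
            betas.append(b)
            variances.append(np.linalg.inv(info))
    logw = np.array(logw)
    w = np.exp(logw - logsumexp(logw))
    betas = np.array(betas)
    bmean = w @ betas
    second = sum(
        wi * (vi + np.outer(bi, bi)) for wi, bi, vi in zip(w, betas, variances)
    )
    cov = second - np.outer(bmean, bmean)
    return bmean, np.sqrt(np.diag(cov))


def reml_random_effects(y, v):
    """Intercept-only normal-normal random-effects model fitted by REML."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)

    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return -0.5 * (
            np.log(w).sum() - np.log(w.sum()) - (w * (y - mu) ** 2).sum()
        )

    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, 10.0 * y.var()),
                          method="bounded")
    tau2 = float(res.x)
    w = 1.0 / (v + tau2)
    mu = float((w * y).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return mu, se, tau2


def weighted_skewness(y, weights):
    y = np.asarray(y, float)
    w = np.asarray(weights, float) / np.asarray(weights, float).sum()
    mu = (w * y).sum()
    m2 = (w * (y - mu) ** 2).sum()
    m3 = (w * (y - mu) ** 3).sum()
    return m3 / m2**1.5
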