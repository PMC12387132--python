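"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's Woodbury-based likelihood code:
each cluster covariance is built as a dense matrix and handled with plain
linear algebra, and the variance components are located by nested grid
refinement of the restricted likelihood rather than quasi-Newton search.
"""

import numpy as np


def restricted_loglik_naive(z, v, clusters, tau2_b, tau2_w):
    """REML log-likelihood (up to constant), dense-matrix evaluation."""
    z = np.asarray(z, float)
    v = np.asarray(v, float)
    clusters = np.asarray(clusters)
    logdet = 0.0
    xtvx = 0.0
    xtvz = 0.0
    quad_parts = []
    for c in np.unique(clusters):
        mask = clusters == c
        zc = z[mask]
        n = zc.size
        V = np.diag(v[mask] + tau2_w) + tau2_b * np.ones((n, n))
        sign, ld = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        one = np.ones(n)
        logdet += ld
        xtvx += one @ Vi @ one
        xtvz += one @ Vi @ zc
        quad_parts.append((zc, Vi, one))
    mu = xtvz / xtvx
    quad = sum((zc - mu) @ Vi @ (zc - mu) for zc, Vi, one in quad_parts)
    return -0.5 * (logdet + np.log(xtvx) + quad), mu, 1.0 / np.sqrt(xtvx)


def reml_grid_search(z, v, clusters, upper=None, n_grid=41, passes=4):
    """Maximize the restricted likelihood by nested 2-D grid refinement."""
    z = np.asarray(z, float)
    if upper is None:
        upper = max(4.0 * float(np.var(z)), 0.5)
    lo_b = lo_w = 0.0
    hi_b = hi_w = upper
    best = None
    for _ in range(passes):
        grid_b = np.linspace(lo_b, hi_b, n_grid)
        grid_w = np.linspace(lo_w, hi_w, n_grid)
        best = None
        for tb in grid_b:
            for tw in grid_w:
                ll, mu, se = restricted_loglik_naive(z, v, clusters, tb, tw)
                if best is None or ll > best[0]:
                    best = (ll, tb, tw, mu, se)
        _, tb, tw, mu, se = best
        step_b = (hi_b - lo_b) / (n_grid - 1)
        step_w = (hi_w - lo_w) / (n_grid - 1)
        lo_b, hi_b = max(0.0, tb - step_b), tb + step_b
        lo_w, hi_w = max(0.0, tw - step_w), tw + step_w
    return {"tau2_between": best[1], "tau2_within": best[2],
            "mu": best[3], "se": best[4], "loglik": best[0]}
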