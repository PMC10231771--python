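"""Independent oracle implementations used only by the test suite.

Everything here is deliberately coded from the model definitions with
plain loops and generic optimizers, independent of the package's
vectorized/closed-form code paths.
"""

from itertools import combinations
from math import log, pi, sqrt

import numpy as np
from scipy.optimize import minimize


def nll_via_density(theta, b_x, r, pair):
    """Negative log-likelihood from the bivariate normal density itself,
    minus the parameter-free constant sum(log(2 pi sx sy sqrt(1-rho^2)))."""
    from scipy.stats import multivariate_normal

    rho = pair.rho
    total = 0.0
    const = 0.0
    for i in range(pair.m):
        sx, sy = pair.se_x[i], pair.se_y[i]
        mean = [b_x[i], theta * b_x[i] + r[i]]
        cov = [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
        total -= multivariate_normal.logpdf([pair.beta_x[i], pair.beta_y[i]], mean, cov)
        const += log(2 * pi * sx * sy * sqrt(1 - rho**2))
    return total - const


def cml_independent_fit(bx, sx, by, sy, K, theta_init, tol=1e-7, max_iter=200):
    """Plain-loop working-independence (rho = 0) constrained MLE.

    Same algorithmic contract (selection by per-SNP likelihood gain,
    closed-form updates, |delta theta| stopping, exact final profile of
    the invalid set) coded scalar-by-scalar from the rho = 0 formulas.
    """
    m = len(bx)
    theta = float(theta_init)
    b = [float(v) for v in bx]
    invalid: list[int] = []
    r = [0.0] * m
    for _ in range(max_iter):
        r_cand = [by[i] - theta * b[i] for i in range(m)]
        if K > 0:
            gains = []
            for i in range(m):
                res_x = (bx[i] - b[i]) / sx[i]
                res_y = (by[i] - theta * b[i]) / sy[i]
                gains.append(0.5 * (res_x**2 + res_y**2) - 0.5 * res_x**2)
            order = sorted(range(m), key=lambda i: (-gains[i], i))
            invalid = sorted(order[:K])
        r = [r_cand[i] if i in invalid else 0.0 for i in range(m)]
        b = [
            (bx[i] / sx[i] ** 2 + theta * (by[i] - r[i]) / sy[i] ** 2)
            / (1.0 / sx[i] ** 2 + theta**2 / sy[i] ** 2)
            for i in range(m)
        ]
        num = sum(b[i] * (by[i] - r[i]) / sy[i] ** 2 for i in range(m))
        den = sum(b[i] ** 2 / sy[i] ** 2 for i in range(m))
        theta_new = num / den
        done = abs(theta_new - theta) < tol
        theta = theta_new
        if done:
            break
    for i in invalid:
        b[i] = bx[i]
        r[i] = by[i] - theta * bx[i]
    nll = sum(
        0.5 * (((bx[i] - b[i]) / sx[i]) ** 2 + ((by[i] - theta * b[i] - r[i]) / sy[i]) ** 2)
        for i in range(m)
    )
    return theta, b, r, invalid, nll


def cml_independent_select(bx, sx, by, sy, n_eff, theta_init, tol=1e-7, max_iter=200):
    """Plain-loop BIC selection over the full K grid at rho = 0."""
    m = len(bx)
    best = None
    for K in range(0, m - 1):
        theta, b, r, invalid, nll = cml_independent_fit(
            bx, sx, by, sy, K, theta_init, tol, max_iter
        )
        bic = 2.0 * nll + log(n_eff) * K
        if best is None or bic < best[0]:
            best = (bic, K, theta, nll)
    return best  # (bic, k_hat, theta, nll)


def _subset_nll_and_grad(params, subset_valid, bx, sx, by, sy, rho):
    """Direct objective/gradient over (theta, bX_valid); invalid SNPs are
    profiled out exactly (their contribution is zero at the optimum)."""
    theta = params[0]
    c = 1.0 / (1.0 - rho**2)
    nll = 0.0
    g_theta = 0.0
    g_b = np.zeros(len(subset_valid))
    for k, i in enumerate(subset_valid):
        b = params[1 + k]
        tx = (bx[i] - b) / sx[i]
        ty = (by[i] - theta * b) / sy[i]
        nll += 0.5 * c * (tx**2 + ty**2 - 2 * rho * tx * ty)
        g_theta += c * (-b * (by[i] - theta * b) / sy[i] ** 2 + rho * b * (bx[i] - b) / (sx[i] * sy[i]))
        g_b[k] = c * (
            -(bx[i] - b) / sx[i] ** 2
            - theta * (by[i] - theta * b) / sy[i] ** 2
            + rho * ((by[i] - theta * b) + theta * (bx[i] - b)) / (sx[i] * sy[i])
        )
    return nll, np.concatenate([[g_theta], g_b])


def exhaustive_cml(pair, K, theta0=None, extra_starts=(0.0, 0.5, -0.5)):
    """Global constrained MLE by enumerating every invalid subset of size K
    and numerically minimizing over (theta, bX_valid) for each subset."""
    m = pair.m
    bx, sx = pair.beta_x, pair.se_x
    by, sy = pair.beta_y, pair.se_y
    rho = pair.rho
    if theta0 is None:
        w = 1.0 / sy**2
        theta0 = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    best = None
    for subset in combinations(range(m), K):
        valid = [i for i in range(m) if i not in subset]
        for t0 in (theta0, *extra_starts):
            x0 = np.concatenate([[t0], bx[valid]])
            res = minimize(
                _subset_nll_and_grad,
                x0,
                args=(valid, bx, sx, by, sy, rho),
                jac=True,
                method="BFGS",
                options={"gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best[0]:
                best = (float(res.fun), float(res.x[0]), subset)
    return best  # (nll, theta, invalid_subset)


def numerical_hessian(f, x0, h=1e-5):
    """Central-difference Hessian of a scalar function."""
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


def power_series_total(D, n_terms=50):
    """Truncated effect series sum_{k=1..n} D^k."""
    D = np.asarray(D, dtype=float)
    acc = np.zeros_like(D)
    term = np.eye(D.shape[0])
    for _ in range(n_terms):
        term = term @ D
        acc += term
    return acc


def char_poly_radius(M):
    """Spectral radius via the characteristic polynomial's roots."""
    coeffs = np.poly(np.asarray(M, dtype=float))
    return float(np.max(np.abs(np.roots(coeffs))))
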