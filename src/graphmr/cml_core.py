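"""Constrained maximum-likelihood MR for one ordered trait pair.

The model: for SNP i with marginal effects b_Xi on the exposure and
b_Yi = theta * b_Xi + r_i on the outcome, the GWAS estimates
(beta_x[i], beta_y[i]) are bivariate normal around (b_Xi, b_Yi) with
standard deviations (se_x[i], se_y[i]) and correlation ``rho`` induced by
overlapping samples.  r_i collects all pleiotropic effects on the outcome
not mediated by the exposure; a SNP is an invalid instrument iff r_i != 0.

The constrained MLE minimizes the negative profile log-likelihood subject
to exactly K of the r_i being nonzero, via a coordinate-descent scheme
with closed-form updates; K is chosen by BIC with N = min(N1, N2).
Under the plurality condition (the largest group of instruments sharing
one causal-parameter value is the valid group) this is consistent for
theta in the presence of invalid instruments.  At rho = 0 the procedure
reduces to the original working-independence estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceWarning, DegenerateModelError, ParameterError
from .gwas_data import SummaryPair

__all__ = [
    "CMLFit",
    "CMLSelection",
    "neg_loglik",
    "update_r",
    "update_b_x",
    "update_theta",
    "fit_fixed_k",
    "select_bic",
    "se_fisher",
    "se_sandwich",
    "ivw_estimate",
]


@dataclass
class CMLFit:
    """Constrained-ML solution at a fixed number K of invalid instruments."""

    theta: float
    b_x: np.ndarray
    r: np.ndarray
    invalid_set: np.ndarray  # sorted SNP indices with r != 0
    loglik: float            # log-likelihood up to constants (<= 0)
    n_iter: int
    converged: bool
    K: int
    nll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.b_x.shape[0], dtype=bool)
        mask[self.invalid_set] = False
        return mask


@dataclass
class CMLSelection:
    """BIC path over K and the selected solution with its standard error."""

    k_grid: list[int]
    bic: dict[int, float]
    k_hat: int
    fit: CMLFit
    se_fisher: float
    se_sandwich: float | None = None
    fits: dict[int, CMLFit] | None = None

    @property
    def pvalue(self) -> float:
        from scipy.stats import norm

        return float(2.0 * norm.sf(abs(self.fit.theta / self.se_fisher)))


def _check_rho(rho: float) -> float:
    if not np.isfinite(rho) or abs(rho) >= 1:
        raise ParameterError(f"|rho| must be < 1 and finite, got {rho}")
    return float(rho)


def _per_snp_nll(theta, b_x, r, bx, sx, by, sy, rho):
    """Per-SNP negative log-likelihood terms (up to constants), vectorized."""
    c = 1.0 / (1.0 - rho * rho)
    tx = (bx - b_x) / sx
    ty = (by - theta * b_x - r) / sy
    return 0.5 * c * (tx * tx + ty * ty - 2.0 * rho * tx * ty)


def neg_loglik(theta: float, b_x: np.ndarray, r: np.ndarray, pair: SummaryPair) -> float:
    """Negative log-likelihood (up to constants) of the bivariate model.

    Equals the sum over SNPs of the standardized quadratic form
    (tx^2 + ty^2 - 2 rho tx ty) / (2 (1 - rho^2)) with
    tx = (beta_x - b_x)/se_x and ty = (beta_y - theta b_x - r)/se_y;
    non-negative, and zero exactly at a perfect fit.
    """
    rho = _check_rho(pair.rho)
    terms = _per_snp_nll(
        float(theta), np.asarray(b_x, float), np.asarray(r, float),
        pair.beta_x, pair.se_x, pair.beta_y, pair.se_y, rho,
    )
    return float(terms.sum())


def update_r(theta: float, b_x: np.ndarray, pair: SummaryPair) -> np.ndarray:
    """Closed-form unconstrained minimizer of the likelihood over each r_i."""
    rho = _check_rho(pair.rho)
    b_x = np.asarray(b_x, float)
    return (pair.beta_y - theta * b_x) - rho * (pair.beta_x - b_x) * pair.se_y / pair.se_x


def update_b_x(theta: float, r: np.ndarray, pair: SummaryPair) -> np.ndarray:
    """Closed-form minimizer over each b_Xi at fixed (theta, r)."""
    rho = _check_rho(pair.rho)
    r = np.asarray(r, float)
    sx, sy = pair.se_x, pair.se_y
    den = 1.0 / sx**2 - 2.0 * rho * theta / (sx * sy) + theta**2 / sy**2
    if np.any(den <= 0):
        raise DegenerateModelError(
            "non-positive quadratic coefficient in the b_X update; "
            "|rho| is too close to 1 for the given theta and SE ratios"
        )
    num = (
        pair.beta_x / sx**2
        - rho * (pair.beta_y - r + theta * pair.beta_x) / (sx * sy)
        + theta * (pair.beta_y - r) / sy**2
    )
    return num / den


def update_theta(b_x: np.ndarray, r: np.ndarray, pair: SummaryPair) -> float:
    """Closed-form minimizer over theta at fixed ({b_Xi}, {r_i})."""
    rho = _check_rho(pair.rho)
    b_x = np.asarray(b_x, float)
    r = np.asarray(r, float)
    sx, sy = pair.se_x, pair.se_y
    den = float(np.sum(b_x**2 / sy**2))
    if den <= 0:
        raise DegenerateModelError("all b_X are zero: no instrument strength")
    num = float(
        np.sum(b_x * (pair.beta_y - r) / sy**2 - rho * b_x * (pair.beta_x - b_x) / (sx * sy))
    )
    return num / den


def ivw_estimate(pair: SummaryPair) -> float:
    """Inverse-variance-weighted ratio estimate, used for initialization."""
    w = 1.0 / pair.se_y**2
    den = float(np.sum(w * pair.beta_x**2))
    if den <= 0:
        raise DegenerateModelError("IVW undefined: all exposure effects are zero")
    return float(np.sum(w * pair.beta_x * pair.beta_y) / den)


def _fit_given_selection(pair, invalid, theta_init, tol, max_iter):
    """Coordinate descent with the invalid set held fixed.

    Iterates the closed-form r (on the fixed set), b_X and theta updates
    to the constrained optimum for this particular subset.
    """
    rho = pair.rho
    bx, sx, by, sy = pair.beta_x, pair.se_x, pair.beta_y, pair.se_y
    m = pair.m
    theta = float(theta_init)
    b_x = bx.copy()
    r = np.zeros(m)
    for _ in range(max_iter):
        r_cand = (by - theta * b_x) - rho * (bx - b_x) * sy / sx
        r = np.zeros(m)
        r[invalid] = r_cand[invalid]
        b_x = update_b_x(theta, r, pair)
        theta_new = update_theta(b_x, r, pair)
        delta = abs(theta_new - theta)
        theta = theta_new
        if delta < tol:
            break
    if len(invalid):
        b_x = b_x.copy()
        b_x[invalid] = bx[invalid]
        r[invalid] = by[invalid] - theta * bx[invalid]
    nll = neg_loglik(theta, b_x, r, pair)
    return theta, b_x, r, nll


def _fixed_theta_snp_cost(pair, theta):
    """Per-SNP profile nll at fixed theta with b_X minimized out.

    For a valid SNP the minimum over b_X of the bivariate quadratic is the
    squared outcome-line residual over its implied variance:
    (beta_y - theta beta_x)^2 / (2 (sy^2 - 2 rho theta sx sy + theta^2 sx^2)).
    Invalid SNPs cost exactly zero (r free).
    """
    sx, sy, rho = pair.se_x, pair.se_y, pair.rho
    denom = sy**2 - 2.0 * rho * theta * sx * sy + theta**2 * sx**2
    return (pair.beta_y - theta * pair.beta_x) ** 2 / (2.0 * denom)


def _swap_refine(pair, fit: CMLFit, tol, max_iter, max_sweeps: int = 20) -> CMLFit:
    """1-swap local search over the invalid set.

    Greedy per-iteration selection can settle on a suboptimal subset.
    Each sweep ranks every exchange of one selected for one unselected SNP
    by the closed-form fixed-theta profile (O(1) per candidate), fully
    re-solves the most promising exchanges, and accepts the best
    improvement; sweeps repeat until no exchange helps.
    """
    if fit.K == 0:
        return fit
    m = pair.m
    best_nll = -fit.loglik
    best = fit
    for _ in range(max_sweeps):
        invalid = sorted(int(i) for i in best.invalid_set)
        inv_set = set(invalid)
        valid = [j for j in range(m) if j not in inv_set]
        cost = _fixed_theta_snp_cost(pair, best.theta)
        # proxy gain of swapping i (in) for j (out): cost[j] - cost[i];
        # refitting can only improve on the fixed-theta bound
        cands = sorted(
            ((cost[j] - cost[i], i, j) for i in invalid for j in valid),
            reverse=True,
        )[:3]
        improved = False
        for _, i, j in cands:
            cand = np.array(sorted(inv_set - {i} | {j}))
            theta, b_x, r, nll = _fit_given_selection(
                pair, cand, best.theta, tol, max_iter
            )
            if nll < best_nll - 1e-12:
                best_nll = nll
                best = CMLFit(
                    theta=theta, b_x=b_x, r=r, invalid_set=cand,
                    loglik=-nll, n_iter=best.n_iter, converged=best.converged,
                    K=fit.K, nll_trace=best.nll_trace,
                )
                improved = True
                break
        if not improved:
            break
    return best


def fit_fixed_k(
    pair: SummaryPair,
    K: int,
    theta_init: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
    refine_swaps: bool = False,
) -> CMLFit:
    """Coordinate-descent constrained MLE with exactly K invalid instruments.

    Alternates (Step 1) the closed-form r update with selection of the K
    SNPs whose free r maximally increases the likelihood, and (Step 2) the
    closed-form b_X and theta updates, until |delta theta| < tol.  Ties in
    the selection gains are broken by SNP index (stable sort).  The
    negative log-likelihood is non-increasing across iterations; a numeric
    increase beyond 1e-10 triggers a warning and termination at the
    previous iterate.  Non-convergence is flagged, not raised.
    """
    m = pair.m
    if not (0 <= K <= m - 2):
        raise ParameterError(f"K must lie in [0, m-2] = [0, {m - 2}], got {K}")
    rho = _check_rho(pair.rho)
    bx, sx, by, sy = pair.beta_x, pair.se_x, pair.beta_y, pair.se_y

    theta = ivw_estimate(pair) if theta_init is None else float(theta_init)
    b_x = bx.copy()
    r = np.zeros(m)
    invalid = np.empty(0, dtype=int)
    prev_state = (theta, b_x.copy(), r.copy(), invalid)
    prev_nll = np.inf
    trace = []
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        # Step 1: candidate r and selection of the K largest likelihood gains
        r_cand = (by - theta * b_x) - rho * (bx - b_x) * sy / sx
        r = np.zeros(m)
        if K > 0:
            nll0 = _per_snp_nll(theta, b_x, 0.0, bx, sx, by, sy, rho)
            # with r free, the per-SNP term collapses to the exposure residual
            nll_free = 0.5 * ((bx - b_x) / sx) ** 2
            gain = nll0 - nll_free  # >= 0: freeing r can only increase l_i
            order = np.argsort(-gain, kind="stable")
            invalid = np.sort(order[:K])
            r[invalid] = r_cand[invalid]
        else:
            invalid = np.empty(0, dtype=int)

        # Step 2: closed-form b_X then theta
        b_x = update_b_x(theta, r, pair)
        theta_new = update_theta(b_x, r, pair)

        nll = neg_loglik(theta_new, b_x, r, pair)
        if nll > prev_nll + 1e-10:
            warnings.warn(
                "fit_fixed_k: likelihood decreased; stopping at previous iterate",
                ConvergenceWarning,
            )
            theta, b_x, r, invalid = prev_state
            nll = prev_nll
            break
        trace.append(nll)
        delta = abs(theta_new - theta)
        prev_state = (theta_new, b_x.copy(), r.copy(), invalid)
        prev_nll = nll
        theta = theta_new
        if delta < tol:
            converged = True
            break

    if K > 0 and invalid.size:
        # exact profile for the selected invalid set: b_X = beta_x and
        # r = beta_y - theta beta_x, which zeroes their likelihood terms and
        # leaves the theta stationarity condition untouched
        b_x = b_x.copy()
        r = r.copy()
        b_x[invalid] = bx[invalid]
        r[invalid] = by[invalid] - theta * bx[invalid]
    nll = neg_loglik(theta, b_x, r, pair)

    fit = CMLFit(
        theta=float(theta),
        b_x=b_x,
        r=r,
        invalid_set=invalid,
        loglik=-nll,
        n_iter=n_iter,
        converged=converged,
        K=K,
        nll_trace=np.asarray(trace),
    )
    if refine_swaps:
        fit = _swap_refine(pair, fit, tol, max_iter)
    return fit


def select_bic(
    pair: SummaryPair,
    k_grid=None,
    n_eff: int | None = None,
    n_starts: int = 10,
    tol: float = 1e-7,
    max_iter: int = 200,
    rng=None,
    keep_fits: bool = False,
    refine_swaps: bool | None = None,
) -> CMLSelection:
    """Fit each K on the grid (multi-start) and select by BIC.

    BIC(K) = -2 l(K) + log(N) K with N = min(N1, N2) unless ``n_eff`` is
    supplied.  Starts are the IVW estimate, a null start, and uniform
    draws on IVW +/- 0.5; the best log-likelihood wins for each K.  BIC
    ties go to the smallest K.  ``refine_swaps`` applies a 1-swap local
    search over the invalid subset (defaults to on for m <= 12, where its
    cost is negligible and the combinatorial selection benefits most).
    """
    m = pair.m
    if k_grid is None:
        k_grid = range(0, m - 1)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ParameterError("k_grid must be non-empty")
    if k_grid[0] < 0 or k_grid[-1] > m - 2:
        raise ParameterError(f"k_grid must be within [0, {m - 2}]")
    if n_eff is None:
        n_eff = min(pair.n_x, pair.n_y)
    if n_eff < 2:
        raise ParameterError("n_eff must be >= 2")
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")

    theta0 = ivw_estimate(pair)
    # IVW start, a null start (the IVW window can miss the truth basin
    # entirely when contamination is gross), then uniform draws around IVW
    starts = [theta0]
    if n_starts > 1:
        starts.append(0.0)
    if n_starts > 2:
        gen = np.random.default_rng(rng)
        starts += list(theta0 + gen.uniform(-0.5, 0.5, size=n_starts - 2))

    if refine_swaps is None:
        refine_swaps = m <= 12
    log_n = np.log(n_eff)
    bic: dict[int, float] = {}
    fits: dict[int, CMLFit] = {}
    for K in k_grid:
        best: CMLFit | None = None
        for s in starts:
            fit = fit_fixed_k(pair, K, theta_init=s, tol=tol, max_iter=max_iter)
            if best is None or fit.loglik > best.loglik:
                best = fit
        assert best is not None
        if refine_swaps:
            # refine only the winning start: the swap search is a local
            # polish, and the best basin is already in hand
            best = _swap_refine(pair, best, tol, max_iter)
        fits[K] = best
        bic[K] = -2.0 * best.loglik + log_n * K

    k_hat = min(bic, key=lambda k: (bic[k], k))
    winner = fits[k_hat]
    try:
        se = se_fisher(winner, pair)
    except DegenerateModelError:
        warnings.warn(
            "select_bic: degenerate information at the BIC winner; SE set to NaN",
            stacklevel=2,
        )
        se = float("nan")
    return CMLSelection(
        k_grid=k_grid,
        bic=bic,
        k_hat=k_hat,
        fit=winner,
        se_fisher=se,
        fits=fits if keep_fits else None,
    )


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def _information_blocks(fit: CMLFit, pair: SummaryPair, rho: float):
    """Observed-information blocks over (theta, {b_Xi : i valid}).

    Invalid instruments are profiled out exactly: their likelihood terms
    reduce to (beta_x - b_x)^2 / (2 se_x^2), contributing no curvature in
    theta, so the information matrix is over 1 + |valid| parameters.
    Returns (h_tt, h_tb, h_bb) with the theta-theta scalar, the
    theta-b_X border vector, and the diagonal of the b_X block.
    """
    valid = fit.valid_mask
    if valid.sum() < 1:
        raise DegenerateModelError("no valid instruments left")
    bx, sx = pair.beta_x[valid], pair.se_x[valid]
    by, sy = pair.beta_y[valid], pair.se_y[valid]
    b = fit.b_x[valid]
    theta = fit.theta
    c = 1.0 / (1.0 - rho * rho)
    h_tt = c * np.sum(b**2 / sy**2)
    h_tb = c * ((2.0 * theta * b - by) / sy**2 + rho * (bx - 2.0 * b) / (sx * sy))
    h_bb = c * (1.0 / sx**2 + theta**2 / sy**2 - 2.0 * rho * theta / (sx * sy))
    return float(h_tt), h_tb, h_bb


def se_fisher(fit: CMLFit, pair: SummaryPair) -> float:
    """Standard error of theta from the observed Fisher information.

    Uses the Schur complement of the b_X block: the (theta, theta) entry
    of the inverse information equals 1 / (h_tt - sum h_tb^2 / h_bb).
    """
    rho = _check_rho(pair.rho)
    h_tt, h_tb, h_bb = _information_blocks(fit, pair, rho)
    if np.any(h_bb <= 0):
        raise DegenerateModelError("singular information matrix (b_X block)")
    schur = h_tt - float(np.sum(h_tb**2 / h_bb))
    if schur <= 0:
        raise DegenerateModelError("singular information matrix (theta block)")
    return float(1.0 / np.sqrt(schur))


def se_sandwich(fit: CMLFit, pair: SummaryPair) -> float:
    """Robust (sandwich) standard error for working-independence fits.

    Intended for fits obtained with rho set to 0 when the true estimate
    correlation may be nonzero: A is the observed information of the
    working (rho = 0) likelihood over (theta, {b_Xi : i valid}); B is the
    variance of the summed score, computed analytically from the linearity
    of the per-SNP scores in (beta_x_i, beta_y_i) under the true bivariate
    covariance with correlation ``pair.rho``.  Returns sqrt of the
    (theta, theta) entry of A^-1 B A^-T.  When rho = 0, B has the same
    structure as A and the two standard errors coincide.
    """
    rho_true = _check_rho(pair.rho)
    valid = fit.valid_mask
    if valid.sum() < 1:
        raise DegenerateModelError("no valid instruments left")
    sx, sy = pair.se_x[valid], pair.se_y[valid]
    b = fit.b_x[valid]
    theta = fit.theta
    v = int(valid.sum())

    # bread: observed information of the rho=0 likelihood
    h_tt, h_tb, h_bb = _information_blocks(fit, pair, 0.0)
    A = np.zeros((1 + v, 1 + v))
    A[0, 0] = h_tt
    A[0, 1:] = h_tb
    A[1:, 0] = h_tb
    A[1:, 1:] = np.diag(h_bb)

    # meat: per-SNP working scores are linear in the data,
    #   s_theta,i  = -(b_i / sy_i^2) beta_y_i + const
    #   s_bX,i     = -(1 / sx_i^2) beta_x_i - (theta / sy_i^2) beta_y_i + const
    # so Var(s_i) follows from the true bivariate covariance of the estimates.
    B = np.zeros((1 + v, 1 + v))
    ct_y = -b / sy**2                        # d s_theta / d beta_y
    cb_x = -1.0 / sx**2                      # d s_b / d beta_x
    cb_y = -theta / sy**2                    # d s_b / d beta_y
    var_x, var_y = sx**2, sy**2
    cov_xy = rho_true * sx * sy
    B[0, 0] = float(np.sum(ct_y**2 * var_y))
    cross = ct_y * (cb_x * cov_xy + cb_y * var_y)
    B[0, 1:] = cross
    B[1:, 0] = cross
    B[1:, 1:] = np.diag(cb_x**2 * var_x + cb_y**2 * var_y + 2.0 * cb_x * cb_y * cov_xy)

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("singular working information matrix") from exc
    var_theta = (Ainv @ B @ Ainv.T)[0, 0]
    if var_theta <= 0:
        raise DegenerateModelError("non-positive sandwich variance")
    return float(np.sqrt(var_theta))


# ---------------------------------------------------------------------------
# Batched engine across perturbations
# ---------------------------------------------------------------------------

def _fit_fixed_k_batch(bx, sx, by, sy, rho, K, theta0, tol=1e-7, max_iter=200):
    """Coordinate descent vectorized over a batch of datasets.

    ``bx, by`` have shape (B, m) (one row per perturbed dataset sharing
    the SE vectors ``sx, sy`` and correlation ``rho``); ``theta0`` has
    shape (B,).  Returns (theta, nll, converged) with shapes (B,), (B,),
    (B,).  Follows the same update order and stable tie-breaking as the
    scalar path; rows keep updating until all have met the tolerance or
    max_iter is reached.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    B, m = bx.shape
    if not (0 <= K <= m - 2):
        raise ParameterError(f"K must lie in [0, m-2], got {K}")
    sx = np.broadcast_to(np.asarray(sx, float), (m,))
    sy = np.broadcast_to(np.asarray(sy, float), (m,))
    inv_sx2 = 1.0 / sx**2
    inv_sy2 = 1.0 / sy**2
    inv_sxsy = 1.0 / (sx * sy)
    ratio_yx = sy / sx

    theta = np.asarray(theta0, float).copy()
    b = bx.copy()
    r = np.zeros_like(bx)
    delta = np.full(B, np.inf)
    for _ in range(max_iter):
        th = theta[:, None]
        r_cand = (by - th * b) - rho * (bx - b) * ratio_yx
        if K > 0:
            c = 1.0 / (1.0 - rho * rho)
            tx = (bx - b) / sx
            ty = (by - th * b) / sy
            nll0 = 0.5 * c * (tx * tx + ty * ty - 2.0 * rho * tx * ty)
            gain = nll0 - 0.5 * tx * tx
            sel = np.argsort(-gain, axis=1, kind="stable")[:, :K]
            r.fill(0.0)
            np.put_along_axis(r, sel, np.take_along_axis(r_cand, sel, axis=1), axis=1)
        den_b = inv_sx2 - 2.0 * rho * th * inv_sxsy + th * th * inv_sy2
        if np.any(den_b <= 0):
            raise DegenerateModelError("non-positive quadratic coefficient in b_X update")
        num_b = (
            bx * inv_sx2
            - rho * (by - r + th * bx) * inv_sxsy
            + th * (by - r) * inv_sy2
        )
        b = num_b / den_b
        num_t = np.sum(b * (by - r) * inv_sy2 - rho * b * (bx - b) * inv_sxsy, axis=1)
        den_t = np.sum(b * b * inv_sy2, axis=1)
        theta_new = num_t / den_t
        delta = np.abs(theta_new - theta)
        theta = theta_new
        if np.all(delta < tol):
            break
    converged = delta < tol

    if K > 0:
        # exact profile of the selected invalid set (matches scalar path)
        sel_mask = r != 0.0
        b = np.where(sel_mask, bx, b)
        r = np.where(sel_mask, by - theta[:, None] * bx, r)
    c = 1.0 / (1.0 - rho * rho)
    tx = (bx - b) / sx
    ty = (by - theta[:, None] * b - r) / sy
    nll = 0.5 * c * np.sum(tx * tx + ty * ty - 2.0 * rho * tx * ty, axis=1)
    return theta, nll, converged


def _select_bic_batch(
    bx, sx, by, sy, rho, n_eff, k_grid=None, theta0=None,
    n_starts: int = 1, rng=None, tol: float = 1e-7, max_iter: int = 200,
):
    """BIC selection across a batch of datasets; returns per-row results.

    ``theta0`` defaults to the per-row IVW estimate; with ``n_starts > 1``
    additional uniform starts on IVW +/- 0.5 are tried and the best
    likelihood wins, mirroring the scalar path.
    Returns (theta, k_hat, bic_min, converged), each of shape (B,).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    B, m = bx.shape
    if k_grid is None:
        k_grid = range(0, m - 1)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 0 or k_grid[-1] > m - 2:
        raise ParameterError(f"k_grid must be a non-empty subset of [0, {m - 2}]")
    sy_arr = np.broadcast_to(np.asarray(sy, float), (m,))
    w = 1.0 / sy_arr**2
    if theta0 is None:
        theta0 = np.sum(w * bx * by, axis=1) / np.sum(w * bx * bx, axis=1)
    starts = [np.asarray(theta0, float)]
    if n_starts > 1:
        starts.append(np.zeros(B))
    if n_starts > 2:
        gen = np.random.default_rng(rng)
        for _ in range(n_starts - 2):
            starts.append(starts[0] + gen.uniform(-0.5, 0.5, size=B))

    log_n = np.log(n_eff)
    best_bic = np.full(B, np.inf)
    best_theta = np.zeros(B)
    best_k = np.zeros(B, dtype=int)
    best_conv = np.zeros(B, dtype=bool)
    for K in k_grid:
        k_nll = np.full(B, np.inf)
        k_theta = np.zeros(B)
        k_conv = np.zeros(B, dtype=bool)
        for s in starts:
            theta, nll, conv = _fit_fixed_k_batch(
                bx, sx, by, sy, rho, K, s, tol=tol, max_iter=max_iter
            )
            better = nll < k_nll
            k_nll = np.where(better, nll, k_nll)
            k_theta = np.where(better, theta, k_theta)
            k_conv = np.where(better, conv, k_conv)
        bic = 2.0 * k_nll + log_n * K
        better = bic < best_bic  # strict: ascending K keeps smallest K on ties
        best_bic = np.where(better, bic, best_bic)
        best_theta = np.where(better, k_theta, best_theta)
        best_k = np.where(better, K, best_k)
        best_conv = np.where(better, k_conv, best_conv)
    return best_theta, best_k, best_bic, best_conv
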